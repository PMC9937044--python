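"""Electroretinogram (ERG) processing: flash responses to sensitivity curves.

The measurement protocol this module analyzes: a dark-adapted eye is given
trains of brief (200 ms) monochromatic flashes.  An intensity series at the
pigment's approximate peak wavelength yields the V/log(I) curve, fitted with
a Naka-Rushton function ``V = Vmax * I^n / (I^n + K^n)``; the half-maximum
intensity from that fit is then used for a wavelength series (5 nm steps,
semi-randomized order).  The response amplitude of each flash is the drop
from the pre-flash baseline to the minimum voltage in the last 10 ms of the
flash; the mean over the final five flashes of a train is the response for
that stimulus.  Per-animal response spectra are smoothed (Savitzky-Golay,
15 nm window), normalized, and averaged into a spectral-sensitivity curve.

Because the response grows sublinearly with intensity, a response spectrum
measured at a fixed intensity is a compressed image of the true sensitivity
spectrum.  ``linearize_responses`` inverts the fitted V/log(I) function to
convert amplitudes to equal-response sensitivities; the high-level
experiment analysis applies it by default when a V/log(I) fit is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.special import expit
from scipy.stats import linregress, spearmanr

__all__ = [
    "ERGTrace",
    "FlashSeries",
    "VlogIFit",
    "SpectralSensitivity",
    "response_amplitude",
    "series_response",
    "fit_vlogi",
    "naka_rushton",
    "linearize_responses",
    "build_sensitivity_curve",
    "stimulus_schedule",
]

LN10 = math.log(10.0)


@dataclass
class ERGTrace:
    """One flash recording: time (s), voltage (mV), and stimulus metadata."""

    time: np.ndarray
    voltage: np.ndarray
    flash_onset: float
    flash_offset: float
    wavelength: float
    photon_flux: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValueError("time and voltage must be 1-D vectors of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] <= self.flash_onset < self.flash_offset <= self.time[-1]):
            raise ValueError("flash window must lie within the recording")


@dataclass
class FlashSeries:
    """Repeated flashes at one wavelength and intensity."""

    traces: list

    def __post_init__(self):
        if not self.traces:
            raise ValueError("FlashSeries needs at least one trace")
        w = {t.wavelength for t in self.traces}
        f = {t.photon_flux for t in self.traces}
        if len(w) > 1 or len(f) > 1:
            raise ValueError("all traces in a series must share wavelength and flux")

    @property
    def n_flashes(self) -> int:
        return len(self.traces)

    @property
    def wavelength(self) -> float:
        return self.traces[0].wavelength

    @property
    def photon_flux(self) -> float:
        return self.traces[0].photon_flux


def response_amplitude(
    trace: ERGTrace, baseline_ms: float = 100.0, window_ms: float = 10.0
) -> float:
    """Photoreceptor response amplitude of one flash, in mV.

    Defined as the drop from the pre-flash baseline (mean voltage over
    ``baseline_ms`` immediately before flash onset) to the minimum voltage in
    the ``window_ms`` immediately before the end of the flash.  Positive for
    the negative-going sustained ERG response; invariant to any constant
    offset of the whole trace.
    """
    t = trace.time
    base_mask = (t >= trace.flash_onset - baseline_ms / 1000.0) & (t < trace.flash_onset)
    win_mask = (t >= trace.flash_offset - window_ms / 1000.0) & (t <= trace.flash_offset)
    if not base_mask.any():
        raise ValueError("no samples in the pre-flash baseline window")
    if not win_mask.any():
        raise ValueError("no samples in the pre-offset analysis window")
    baseline = float(trace.voltage[base_mask].mean())
    vmin = float(trace.voltage[win_mask].min())
    return baseline - vmin


def series_response(series: FlashSeries, n_last: int = 5, **amp_kwargs) -> float:
    """Mean response amplitude over the final ``n_last`` flashes of a train."""
    if series.n_flashes < n_last:
        raise ValueError(
            f"series has {series.n_flashes} flashes, need at least {n_last}"
        )
    amps = [response_amplitude(tr, **amp_kwargs) for tr in series.traces[-n_last:]]
    return float(np.mean(amps))


def naka_rushton(intensity, v_max: float, K: float, n: float):
    """Naka-Rushton intensity-response function V = Vmax*I^n/(I^n + K^n)."""
    intensity = np.asarray(intensity, dtype=float)
    # expit form is overflow-safe: V = Vmax * expit(n*ln10*(log10 I - log10 K))
    return v_max * expit(n * LN10 * (np.log10(intensity) - math.log10(K)))


@dataclass
class VlogIFit:
    """Fitted intensity-response function and derived test intensity."""

    v_max: float
    K: float  # half-saturating intensity, photons/cm^2/s
    n_exp: float
    model: str  # "naka_rushton" or "sigmoid"
    saturated: bool
    test_intensity: float
    adjusted_r2: float
    converged: bool = True
    intensity_range: tuple = (0.0, 0.0)

    def predict(self, intensity) -> np.ndarray:
        return naka_rushton(intensity, self.v_max, self.K, self.n_exp)

    def inverse(self, response) -> np.ndarray:
        """Intensity producing a given response (clipped below saturation)."""
        v = np.clip(np.asarray(response, dtype=float), 1e-9 * self.v_max, 0.999 * self.v_max)
        return self.K * (v / (self.v_max - v)) ** (1.0 / self.n_exp)

    def to_dict(self) -> dict:
        return {
            "v_max_mV": self.v_max,
            "K_photons_cm2_s": self.K,
            "n_exp": self.n_exp,
            "model": self.model,
            "saturated": self.saturated,
            "test_intensity_photons_cm2_s": self.test_intensity,
            "adjusted_r2": self.adjusted_r2,
            "converged": self.converged,
        }


def _linear_stretch_midpoint(x: np.ndarray, y: np.ndarray) -> float:
    """Midpoint (in x) of the longest log-linear run with R^2 >= 0.98."""
    n = x.size
    best = None  # (length, r2, mid)
    for i in range(n - 2):
        for j in range(i + 2, n):
            r = linregress(x[i : j + 1], y[i : j + 1])
            r2 = r.rvalue**2
            if r2 >= 0.98:
                cand = (j - i + 1, r2, 0.5 * (x[i] + x[j]))
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is None:
        # fall back to the best 3-point window
        r2s = [
            (linregress(x[i : i + 3], y[i : i + 3]).rvalue ** 2, 0.5 * (x[i] + x[i + 2]))
            for i in range(n - 2)
        ]
        best = (3,) + max(r2s)
    return best[-1]


def fit_vlogi(intensities, responses, model: str = "naka_rushton") -> VlogIFit:
    """Fit an intensity-response function on the log10-intensity axis.

    ``model`` is ``"naka_rushton"``, ``"sigmoid"`` (a logistic in log10 I —
    mathematically the Naka-Rushton family reparameterized, kept as a
    separate surface for protocol parity), or ``"auto"`` (higher adjusted
    R^2 wins; Naka-Rushton preferred on ties).

    ``saturated`` is set when the fitted plateau is no more than 1.2x the
    largest observed response; the derived ``test_intensity`` is the
    half-maximum intensity K when saturated, otherwise the midpoint of the
    largest log-linear stretch of the curve.
    """
    I = np.asarray(intensities, dtype=float)
    V = np.asarray(responses, dtype=float)
    if I.ndim != 1 or I.shape != V.shape:
        raise ValueError("intensities and responses must be 1-D and equal length")
    if I.size < 4:
        raise ValueError("need at least 4 intensity levels")
    if np.any(np.diff(I) <= 0):
        raise ValueError("intensities must be strictly increasing")
    if np.any(V < 0) or not np.all(np.isfinite(V)):
        raise ValueError("responses must be finite and non-negative")
    rho = spearmanr(I, V).statistic
    if rho < 0:
        raise ValueError("responses decrease with intensity (Spearman rho < 0)")

    x = np.log10(I)
    vmax0 = 1.05 * float(V.max())
    half = 0.5 * V.max()
    logk0 = float(np.interp(half, V, x)) if V.max() > 0 else float(x.mean())

    if model == "auto":
        fits = []
        for m in ("naka_rushton", "sigmoid"):
            try:
                fits.append(fit_vlogi(I, V, m))
            except RuntimeError:
                pass
        if not fits:
            raise RuntimeError("neither model converged")
        # Naka-Rushton first, so strict '>' keeps it on ties
        return max(fits, key=lambda f: (f.adjusted_r2, f.model == "naka_rushton"))

    if model == "naka_rushton":
        def f(xv, vmax, logk, n):
            return vmax * expit(n * LN10 * (xv - logk))
    elif model == "sigmoid":
        def f(xv, vmax, x0, s):
            return vmax * expit((xv - x0) / s)
    else:
        raise ValueError(f"unknown model: {model!r}")

    slope0 = 1.0 if model == "naka_rushton" else 1.0 / LN10
    lb = [1e-9, x.min() - 6.0, 1e-3]
    ub = [np.inf, x.max() + 6.0, 50.0]
    # multi-start: a saturating start and a shallow/unsaturated start, so
    # strictly linear data is not trapped at a spuriously saturating optimum
    starts = [
        [vmax0, logk0, slope0],
        [3.0 * float(V.max()) + 1e-9, x.max(), 0.3 * slope0],
    ]
    converged = False
    popt, best_sse = None, np.inf
    for p0 in starts:
        try:
            cand, _ = curve_fit(f, x, V, p0=p0, bounds=(lb, ub), maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((V - f(x, *cand)) ** 2))
        if sse < best_sse:
            popt, best_sse, converged = cand, sse, True
    if popt is None:
        popt = np.array(starts[0])
    vmax_hat, p1, p2 = (float(v) for v in popt)
    if model == "naka_rushton":
        K, n_exp = 10.0**p1, p2
    else:
        K, n_exp = 10.0**p1, 1.0 / (p2 * LN10)

    pred = f(x, *popt)
    try:
        adj = _adjusted_r2(V, pred, 3)
    except ValueError:
        adj = float("nan")
    # saturation: fitted plateau close to the observed maximum AND the fitted
    # curve actually flattens at the top of the tested range (a logistic fit
    # to strictly linear data satisfies the first test but not the second)
    slopes = np.diff(pred) / np.diff(x)
    top_flat = slopes[-1] <= 0.5 * slopes.max() if slopes.max() > 0 else False
    saturated = converged and vmax_hat <= 1.2 * float(V.max()) and bool(top_flat)
    if saturated:
        test_intensity = K
    else:
        test_intensity = 10.0 ** _linear_stretch_midpoint(x, V)
    return VlogIFit(
        v_max=vmax_hat,
        K=K,
        n_exp=n_exp,
        model=model,
        saturated=saturated,
        test_intensity=float(test_intensity),
        adjusted_r2=adj,
        converged=converged,
        intensity_range=(float(I.min()), float(I.max())),
    )


def _adjusted_r2(y, yhat, p):
    from .templates import adjusted_r_squared

    return adjusted_r_squared(y, yhat, p)


def linearize_responses(responses, vlogi: VlogIFit, test_intensity: float | None = None):
    """Convert response amplitudes at a fixed intensity to relative sensitivities.

    Inverts the fitted V/log(I) function: the sensitivity at a wavelength is
    proportional to the intensity that would be needed to evoke the observed
    response, relative to the intensity actually used,
    ``S = f^-1(V) / I_test``.
    """
    I0 = float(test_intensity if test_intensity is not None else vlogi.test_intensity)
    if I0 <= 0:
        raise ValueError("test intensity must be positive")
    v = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    return vlogi.inverse(v) / I0


@dataclass
class SpectralSensitivity:
    """Averaged, normalized wavelength-sensitivity curve."""

    wavelengths: np.ndarray
    mean_sensitivity: np.ndarray
    sd: np.ndarray
    n_animals: int
    testing_range: tuple

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean_sensitivity = np.asarray(self.mean_sensitivity, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)


def build_sensitivity_curve(
    per_animal: Sequence,
    window_nm: float = 15.0,
    polyorder: int = 1,
    vlogi_fits: Sequence[VlogIFit] | None = None,
    test_intensity: float | None = None,
) -> SpectralSensitivity:
    """Combine per-animal (wavelength, response) series into a final curve.

    Per series: optional equal-response linearization through that animal's
    V/log(I) fit, Savitzky-Golay smoothing with a window spanning
    ``window_nm`` of the grid, then division by the series maximum.  The
    normalized series are averaged across animals, the standard deviation is
    computed, and the mean is renormalized to [0, 1].

    ``per_animal`` is a sequence of ``(wavelengths, responses)`` pairs
    sharing one wavelength grid.  ``vlogi_fits`` (one per animal, or a
    single fit reused for all) enables linearization.
    """
    if len(per_animal) < 1:
        raise ValueError("need at least one animal")
    lam0 = np.asarray(per_animal[0][0], dtype=float)
    if lam0.ndim != 1 or np.any(np.diff(lam0) <= 0):
        raise ValueError("wavelength grid must be 1-D, sorted, unique")
    steps = np.diff(lam0)
    step = float(steps[0])
    if not np.allclose(steps, step):
        raise ValueError("wavelength grid must be evenly spaced")
    if window_nm > lam0[-1] - lam0[0]:
        raise ValueError("smoothing window larger than the wavelength span")
    win = int(round(window_nm / step))
    if win % 2 == 0:
        win += 1
    win = max(win, 3)
    poly = min(polyorder, win - 1)

    if vlogi_fits is not None and not isinstance(vlogi_fits, (list, tuple)):
        vlogi_fits = [vlogi_fits] * len(per_animal)
    if vlogi_fits is not None and len(vlogi_fits) != len(per_animal):
        raise ValueError("need one V/logI fit per animal (or a single shared fit)")

    normed = []
    for i, (lam, resp) in enumerate(per_animal):
        lam = np.asarray(lam, dtype=float)
        resp = np.asarray(resp, dtype=float)
        if lam.shape != lam0.shape or not np.allclose(lam, lam0):
            raise ValueError("all animals must share the same wavelength grid")
        if not np.all(np.isfinite(resp)):
            raise ValueError("non-finite response values")
        if vlogi_fits is not None:
            resp = linearize_responses(resp, vlogi_fits[i], test_intensity)
        sm = savgol_filter(resp, win, poly)
        m = sm.max()
        if m <= 0:
            raise ValueError("non-positive series maximum after smoothing")
        normed.append(sm / m)
    arr = np.vstack(normed)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    mean = np.clip(mean, 0.0, None)
    peak = mean.max()
    return SpectralSensitivity(
        wavelengths=lam0,
        mean_sensitivity=mean / peak,
        sd=sd / peak,
        n_animals=len(per_animal),
        testing_range=(float(lam0[0]), float(lam0[-1])),
    )


def stimulus_schedule(lambda_lo: float, lambda_hi: float, step: float, seed) -> np.ndarray:
    """Semi-randomized wavelength presentation order.

    Wavelengths are split into three contiguous groups (low, mid, high),
    shuffled within each group, and presented cycling low -> mid -> high so
    the session is balanced over the spectrum.  Every wavelength appears
    exactly once; deterministic for a fixed seed.
    """
    if lambda_hi <= lambda_lo:
        raise ValueError("empty wavelength range")
    n_steps = (lambda_hi - lambda_lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("(hi - lo) must be divisible by step")
    lams = lambda_lo + step * np.arange(int(round(n_steps)) + 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = [rng.permutation(g) for g in np.array_split(lams, 3)]
    out = []
    for k in range(max(len(g) for g in groups)):
        for g in groups:
            if k < len(g):
                out.append(float(g[k]))
    return np.array(out, dtype=float)
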