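"""Synthetic ERG experiments and opsin sequence families with known truth.

The photoreceptor model behind the trace generator is the implicit model of
the measurement itself: spectral sensitivity follows a visual-pigment
template ``S(lambda)`` at a chosen true ``lambda_max``, and the sustained
response depth to a flash of photon flux ``I`` is the Naka-Rushton
saturation of the effective catch,

    V = Vmax * (S*I)^n / ((S*I)^n + K^n).

Waveforms carry a fast positive on-transient and negative off-transient
(raised-cosine bumps, 20 ms) flanking the sustained negative plateau, plus
i.i.d. Gaussian sample noise, emulating the fly ERG.  Transients sit outside
the 10-0 ms pre-offset amplitude window, so on noiseless traces the pipeline
amplitude equals the analytic plateau depth exactly.

Per-animal variability: a log-normal scale factor on Vmax and Gaussian
jitter on the per-wavelength sensitivity.  All generators are deterministic
under a fixed seed, and every dataset ships with a ``GroundTruthManifest``.

``simulate_opsin_family`` plants duplicate-divergent, ortholog-invariant
substitutions at chosen pocket sites in a random amino-acid family, with
invariant decoy pocket sites and background divergence between species —
the structure the tuning-site screen is designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .erg import ERGTrace, FlashSeries, stimulus_schedule
from .templates import SpectralTemplate, evaluate_template

__all__ = [
    "FlashProtocol",
    "PhotoreceptorModel",
    "GroundTruthManifest",
    "ERGExperiment",
    "simulate_trace",
    "simulate_flash_series",
    "simulate_vlogi_series",
    "simulate_experiment",
    "simulate_opsin_family",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Paper-protocol intensity range for V/log(I) series, photons/cm^2/s.
VLOGI_INTENSITY_RANGE = (1.14e12, 3.60e16)


@dataclass(frozen=True)
class FlashProtocol:
    """Flash timing: 200 ms flashes, simulated with pre/post context."""

    flash_ms: float = 200.0
    pre_ms: float = 200.0
    post_ms: float = 100.0
    n_flashes: int = 10
    interflash_s: float = 5.0
    sampling_hz: float = 1000.0

    @property
    def onset_s(self) -> float:
        return self.pre_ms / 1000.0

    @property
    def offset_s(self) -> float:
        return (self.pre_ms + self.flash_ms) / 1000.0

    @property
    def duration_s(self) -> float:
        return (self.pre_ms + self.flash_ms + self.post_ms) / 1000.0


@dataclass(frozen=True)
class PhotoreceptorModel:
    """Ground-truth photoreceptor: template sensitivity x Naka-Rushton."""

    template: SpectralTemplate
    v_max: float = 12.0  # mV
    K: float = 1.0e14  # photons/cm^2/s at unit sensitivity
    n_exp: float = 0.8
    transient_amp: float = 3.0  # mV
    noise_sd: float = 0.1  # mV per sample
    adapt_frac: float = 0.3  # initial flashes elevated by this fraction
    adapt_tau: float = 1.5  # e-fold decay of adaptation, in flashes
    vmax_animal_sd: float = 0.2  # sigma of log-normal per-animal Vmax scale

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def sensitivity(self, wavelength: float) -> float:
        return evaluate_template(self.template, np.array([wavelength])).item(0)

    def plateau_depth(self, wavelength: float, flux: float, amp_scale: float = 1.0) -> float:
        """Analytic sustained response depth (mV) for one stimulus."""
        if flux <= 0:
            raise ValueError("photon flux must be positive")
        eff = self.sensitivity(wavelength) * flux
        with np.errstate(over="ignore"):
            frac = 1.0 / (1.0 + (self.K / eff) ** self.n_exp)
        return self.v_max * amp_scale * frac


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-amplitude raised-cosine bump supported on [center +- width/2]."""
    z = (t - center) / (width / 2.0)
    bump = 0.5 * (1.0 + np.cos(np.pi * np.clip(z, -1.0, 1.0)))
    bump[np.abs(z) >= 1.0] = 0.0
    return bump


def _plateau_shape(t: np.ndarray, onset: float, offset: float, edge: float) -> np.ndarray:
    """0 before onset, raised-cosine rise over ``edge`` s, 1 until offset, decay."""
    shape = np.zeros_like(t)
    rise = (t >= onset) & (t < onset + edge)
    shape[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - onset) / edge))
    shape[(t >= onset + edge) & (t <= offset)] = 1.0
    fall = (t > offset) & (t < offset + edge)
    shape[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - offset) / edge))
    return shape


def simulate_trace(
    model: PhotoreceptorModel,
    wavelength: float,
    flux: float,
    protocol: FlashProtocol = FlashProtocol(),
    rng: np.random.Generator | int | None = 0,
    amp_scale: float = 1.0,
) -> ERGTrace:
    """One synthetic ERG flash trace; deterministic for a fixed seed/rng."""
    if flux <= 0:
        raise ValueError("photon flux must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    dt = 1.0 / protocol.sampling_hz
    t = np.arange(0.0, protocol.duration_s + dt / 2, dt)
    onset, offset = protocol.onset_s, protocol.offset_s
    depth = model.plateau_depth(wavelength, flux, amp_scale)
    edge = 0.020  # 20 ms plateau edges and transient width
    v = -depth * _plateau_shape(t, onset, offset, edge)
    v += model.transient_amp * _raised_cosine(t, onset + edge / 2, edge)
    v -= model.transient_amp * _raised_cosine(t, offset + edge / 2 + dt, edge)
    if model.noise_sd > 0:
        v = v + rng.normal(0.0, model.noise_sd, size=t.size)
    return ERGTrace(
        time=t,
        voltage=v,
        flash_onset=onset,
        flash_offset=offset,
        wavelength=wavelength,
        photon_flux=flux,
    )


def _adapt_scales(model: PhotoreceptorModel, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 1.0 + model.adapt_frac * np.exp(-k / model.adapt_tau)


def simulate_flash_series(
    model: PhotoreceptorModel,
    wavelength: float,
    flux: float,
    protocol: FlashProtocol = FlashProtocol(),
    rng: np.random.Generator | int | None = 0,
    amp_scale: float = 1.0,
) -> tuple[FlashSeries, np.ndarray]:
    """A train of flashes with light-adaptation decay; returns the series and
    the analytic per-flash plateau depths (ground truth)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    scales = _adapt_scales(model, protocol.n_flashes)
    traces, truth = [], []
    for s in scales:
        tr = simulate_trace(model, wavelength, flux, protocol, rng, amp_scale * s)
        traces.append(tr)
        truth.append(model.plateau_depth(wavelength, flux, amp_scale * s))
    return FlashSeries(traces), np.array(truth)


def simulate_vlogi_series(
    model: PhotoreceptorModel,
    wavelength: float,
    intensities=None,
    rng: np.random.Generator | int | None = 0,
    amp_scale: float = 1.0,
    response_noise_sd: float = 0.0,
):
    """Amplitude-level intensity series at one wavelength.

    Returns ``(intensities, responses)`` where responses are the analytic
    steady-state amplitudes plus optional Gaussian noise.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if intensities is None:
        intensities = np.geomspace(*VLOGI_INTENSITY_RANGE, 9)
    I = np.asarray(intensities, dtype=float)
    V = np.array([model.plateau_depth(wavelength, i, amp_scale) for i in I])
    if response_noise_sd > 0:
        V = np.clip(V + rng.normal(0.0, response_noise_sd, I.size), 0.0, None)
    return I, V


@dataclass
class GroundTruthManifest:
    """Everything needed to reproduce and check a synthetic experiment."""

    true_lambda_max: float
    family: str
    beta_band: bool
    true_v_max: float
    true_K: float
    true_n_exp: float
    seed: int
    test_flux: float
    wavelengths: list
    animal_vmax_scales: list
    true_sensitivity: list  # template values on the grid (no jitter)
    true_amplitudes: dict  # animal -> per-wavelength asymptotic amplitude
    per_flash_scales: list  # adaptation scale of each flash in a train

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


@dataclass
class ERGExperiment:
    """Synthetic dataset: per-animal spectral series plus a V/logI series."""

    amplitudes: dict  # animal_id -> {"wavelengths": arr, "responses": arr}
    series: dict | None  # animal_id -> {wavelength: FlashSeries}, trace level only
    vlogi: dict  # animal_id -> (intensities, responses)
    manifest: GroundTruthManifest

    def per_animal(self) -> list:
        return [
            (np.asarray(a["wavelengths"]), np.asarray(a["responses"]))
            for a in self.amplitudes.values()
        ]


def simulate_experiment(
    model: PhotoreceptorModel,
    n_animals: int = 6,
    testing_range: tuple = (315.0, 550.0),
    step: float = 5.0,
    protocol: FlashProtocol = FlashProtocol(),
    seed: int = 0,
    sensitivity_noise_sd: float = 0.05,
    level: str = "trace",
    test_flux: float | None = None,
) -> ERGExperiment:
    """Simulate a full spectral-sensitivity experiment.

    Per animal: a V/log(I) series at the wavelength nearest the true peak,
    then a semi-randomized wavelength series at the half-saturating flux
    (``test_flux`` defaults to the model's true K, the flux at which the
    peak-wavelength response is half-maximal).  ``level`` is ``"trace"``
    (full waveforms; the pipeline must extract amplitudes) or
    ``"amplitude"`` (analytic steady-state amplitudes with the same
    per-animal and per-wavelength variability, for cheap replication
    studies).
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    if level not in ("trace", "amplitude"):
        raise ValueError("level must be 'trace' or 'amplitude'")
    rng = np.random.default_rng(seed)
    lo, hi = testing_range
    lams = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    S_true = evaluate_template(model.template, lams)
    peak_lam = float(lams[int(np.argmax(S_true))])
    flux = float(test_flux if test_flux is not None else model.K)

    vmax_scales = np.exp(rng.normal(0.0, model.vmax_animal_sd, n_animals))
    amplitudes, series, vlogi, true_amp = {}, {}, {}, {}
    n_last_scale = 1.0  # asymptotic amplitude reference
    for a in range(n_animals):
        aid = f"animal{a + 1}"
        scale = float(vmax_scales[a])
        vI, vV = simulate_vlogi_series(
            model, peak_lam, rng=rng, amp_scale=scale,
            response_noise_sd=model.noise_sd,
        )
        vlogi[aid] = (vI, vV)
        order = stimulus_schedule(lo, hi, step, rng)
        jitter = dict(
            zip(lams, np.clip(S_true + rng.normal(0.0, sensitivity_noise_sd, lams.size),
                              1e-6, None))
        )
        resp = {}
        ser = {}
        truth = {}
        for lam in order:
            s_eff = jitter[lam]
            eff_model_sens = s_eff  # jittered sensitivity for this animal/wavelength
            depth_asym = _depth(model, eff_model_sens, flux, scale)
            truth[lam] = depth_asym
            if level == "trace":
                fs, _ = _simulate_series_at_sensitivity(
                    model, lam, s_eff, flux, protocol, rng, scale
                )
                ser[lam] = fs
                from .erg import series_response

                resp[lam] = series_response(fs)
            else:
                # mean of the final five analytic per-flash amplitudes + noise
                scales5 = _adapt_scales(model, protocol.n_flashes)[-5:]
                amps = np.array([_depth(model, s_eff, flux, scale * s) for s in scales5])
                if model.noise_sd > 0:
                    amps = amps + rng.normal(0.0, model.noise_sd, amps.size)
                resp[lam] = float(np.mean(amps))
        amplitudes[aid] = {
            "wavelengths": lams.copy(),
            "responses": np.array([resp[lam] for lam in lams]),
        }
        if level == "trace":
            series[aid] = ser
        true_amp[aid] = [truth[lam] for lam in lams]

    manifest = GroundTruthManifest(
        true_lambda_max=model.template.lambda_max,
        family=model.template.family,
        beta_band=model.template.beta_band,
        true_v_max=model.v_max,
        true_K=model.K,
        true_n_exp=model.n_exp,
        seed=seed,
        test_flux=flux,
        wavelengths=[float(x) for x in lams],
        animal_vmax_scales=[float(x) for x in vmax_scales],
        true_sensitivity=[float(x) for x in S_true],
        true_amplitudes={k: [float(x) for x in v] for k, v in true_amp.items()},
        per_flash_scales=[float(x) for x in _adapt_scales(model, protocol.n_flashes)],
    )
    return ERGExperiment(
        amplitudes=amplitudes,
        series=series if level == "trace" else None,
        vlogi=vlogi,
        manifest=manifest,
    )


def _depth(model: PhotoreceptorModel, sensitivity: float, flux: float, amp_scale: float) -> float:
    eff = sensitivity * flux
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + (model.K / eff) ** model.n_exp)
    return model.v_max * amp_scale * frac


def _simulate_series_at_sensitivity(
    model, wavelength, sensitivity, flux, protocol, rng, amp_scale
):
    """Flash train where the sensitivity at this wavelength is overridden
    (per-animal spectral jitter)."""
    scales = _adapt_scales(model, protocol.n_flashes)
    dt = 1.0 / protocol.sampling_hz
    t = np.arange(0.0, protocol.duration_s + dt / 2, dt)
    onset, offset = protocol.onset_s, protocol.offset_s
    edge = 0.020
    shape = _plateau_shape(t, onset, offset, edge)
    on_b = _raised_cosine(t, onset + edge / 2, edge)
    off_b = _raised_cosine(t, offset + edge / 2 + dt, edge)
    traces, truth = [], []
    for s in scales:
        depth = _depth(model, sensitivity, flux, amp_scale * s)
        v = -depth * shape + model.transient_amp * (on_b - off_b)
        if model.noise_sd > 0:
            v = v + rng.normal(0.0, model.noise_sd, t.size)
        traces.append(
            ERGTrace(t, v, onset, offset, wavelength=wavelength, photon_flux=flux)
        )
        truth.append(depth)
    return FlashSeries(traces), np.array(truth)


def simulate_opsin_family(
    base_length: int = 330,
    n_species: int = 2,
    planted_sites: list | None = None,
    pocket_decoys: int = 5,
    background_rate: float = 0.05,
    seed: int = 0,
    species_names: list | None = None,
    copy_labels: tuple = ("copy1", "copy2"),
):
    """Generate an opsin duplicate family with planted tuning sites.

    ``planted_sites`` is a list of ``(position, aa_copy1, aa_copy2)`` with
    1-based positions; at those sites every species carries ``aa_copy1`` in
    the first duplicate and ``aa_copy2`` in the second (variant between
    duplicates, invariant across species).  ``pocket_decoys`` additional
    pocket positions are invariant everywhere.  Background positions mutate
    independently per species at ``background_rate`` (applied identically to
    both copies of that species, emulating post-duplication speciation
    divergence).

    Returns ``(OpsinSet, pocket_positions)`` where ``pocket_positions`` is
    the sorted list of planted + decoy 1-based positions.
    """
    from .screen import OpsinSet

    planted_sites = planted_sites or []
    rng = np.random.default_rng(seed)
    positions = [p for p, _, _ in planted_sites]
    if len(set(positions)) != len(positions):
        raise ValueError("planted positions must be distinct")
    if any(not (1 <= p <= base_length) for p in positions):
        raise ValueError("planted positions must lie within the sequence")
    aas = np.array(list(AMINO_ACIDS))
    base = rng.choice(aas, size=base_length)

    free = np.setdiff1d(np.arange(1, base_length + 1), np.array(positions, dtype=int))
    if pocket_decoys > free.size:
        raise ValueError("more decoys than available positions")
    decoys = np.sort(rng.choice(free, size=pocket_decoys, replace=False))
    if set(decoys) & set(positions):
        raise ValueError("planted positions collide with decoys")
    pocket_positions = sorted(positions + [int(d) for d in decoys])
    protected = set(pocket_positions)

    if species_names is None:
        species_names = [f"species{chr(ord('A') + i)}" for i in range(n_species)]
    sequences = {}
    for sp in species_names:
        seq = base.copy()
        for pos in range(1, base_length + 1):
            if pos in protected:
                continue
            if rng.random() < background_rate:
                alt = rng.choice(aas[aas != seq[pos - 1]])
                seq[pos - 1] = alt
        for copy_i, label in enumerate(copy_labels):
            cseq = seq.copy()
            for pos, aa1, aa2 in planted_sites:
                cseq[pos - 1] = aa1 if copy_i == 0 else aa2
            sequences[(sp, label)] = "".join(cseq)
    opsins = OpsinSet(sequences=sequences, alignment=dict(sequences))
    return opsins, pocket_positions
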