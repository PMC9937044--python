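"""Visual-pigment absorbance templates and lambda-max estimation.

A visual pigment's normalized absorbance (and, to good approximation, the
spectral sensitivity of a photoreceptor expressing it) is a near-universal
function of wavelength once the peak wavelength ``lambda_max`` is known.
Two parametric template families are implemented:

``govardovskii_a1``
    The A1 (retinal) nomogram of Govardovskii and colleagues: an alpha band
    written as a reciprocal-exponential function of ``lambda_max / lambda``
    plus a Gaussian beta band whose position and width scale with
    ``lambda_max``.

``stavenga_band``
    The exponential ("modified Gaussian") absorbance-band model of Stavenga
    and colleagues: each band is ``exp(-a x^2 (1 + b x + c x^2))`` with
    ``x = log10(lambda / lambda_band)``; the alpha band peaks at
    ``lambda_max`` and a fixed-position beta band may be superposed.

Fitting a template to a measured spectral-sensitivity curve has two free
parameters, ``lambda_max`` and a linear scale; goodness of fit is reported
as an adjusted R-squared penalized for those two parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "SpectralTemplate",
    "TemplateFit",
    "TEMPLATE_COEFFICIENTS",
    "evaluate_template",
    "template_peak",
    "fit_template",
    "adjusted_r_squared",
    "lambda_max_shift",
]

FAMILIES = ("govardovskii_a1", "stavenga_band")

#: Versioned coefficient table for the two template families.  Users may pass
#: an edited copy to :class:`SpectralTemplate` via ``band_coefficients`` if a
#: different transcription of the source equations is preferred.
TEMPLATE_COEFFICIENTS: dict = {
    "version": 1,
    "govardovskii_a1": {
        # alpha band: S(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)
        # with x = lambda_max / lambda and a = a0 + a1*exp(-(lmax-300)^2/11940)
        "A": 69.7,
        "B": 28.0,
        "C": -14.9,
        "D": 0.674,
        "b": 0.922,
        "c": 1.104,
        "a0": 0.8795,
        "a1": 0.0459,
        "a_lref": 300.0,
        "a_denom": 11940.0,
        # beta band: A_beta * exp(-((lambda - lmb)/bw)^2),
        # lmb = 189 + 0.315*lmax ; bw = -40.5 + 0.195*lmax
        "beta_amp": 0.26,
        "beta_lmb0": 189.0,
        "beta_lmb1": 0.315,
        "beta_bw0": -40.5,
        "beta_bw1": 0.195,
    },
    "stavenga_band": {
        # band shape: exp(-a x^2 (1 + b x + c x^2)), x = log10(lambda/lambda_band)
        "alpha": {"a": 380.0, "b": 6.09, "c": 26.1},
        "beta": {"a": 247.0, "b": 3.59, "c": 0.0, "amp": 0.29, "lambda": 350.0},
    },
}

# Supported lambda_max range per family (nm).
_FAMILY_RANGE = {
    "govardovskii_a1": (330.0, 700.0),
    "stavenga_band": (300.0, 700.0),
}

_DENSE_STEP = 0.1
_DENSE_RANGE = (300.0, 700.0)


@dataclass(frozen=True)
class SpectralTemplate:
    """A visual-pigment template: family, peak wavelength, beta-band flag."""

    family: str
    lambda_max: float
    beta_band: bool = True
    band_coefficients: dict = field(default_factory=lambda: TEMPLATE_COEFFICIENTS)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown template family: {self.family!r}")
        lo, hi = _FAMILY_RANGE[self.family]
        if not (lo <= self.lambda_max <= hi):
            raise ValueError(
                f"lambda_max {self.lambda_max} nm outside supported range "
                f"[{lo}, {hi}] for family {self.family}"
            )

    def __call__(self, wavelengths) -> np.ndarray:
        return evaluate_template(self, wavelengths)


def _raw_template(template: SpectralTemplate, lam: np.ndarray) -> np.ndarray:
    """Un-normalized template value (alpha + optional beta band)."""
    lmax = template.lambda_max
    if template.family == "govardovskii_a1":
        c = template.band_coefficients["govardovskii_a1"]
        x = lmax / lam
        a = c["a0"] + c["a1"] * np.exp(-((lmax - c["a_lref"]) ** 2) / c["a_denom"])
        alpha = 1.0 / (
            np.exp(c["A"] * (a - x))
            + np.exp(c["B"] * (c["b"] - x))
            + np.exp(c["C"] * (c["c"] - x))
            + c["D"]
        )
        if not template.beta_band:
            return alpha
        lmb = c["beta_lmb0"] + c["beta_lmb1"] * lmax
        bw = c["beta_bw0"] + c["beta_bw1"] * lmax
        beta = c["beta_amp"] * np.exp(-(((lam - lmb) / bw) ** 2))
        return alpha + beta
    # stavenga_band
    c = template.band_coefficients["stavenga_band"]

    def band(lam_band: float, p: dict) -> np.ndarray:
        x = np.log10(lam / lam_band)
        return np.exp(-p["a"] * x**2 * (1.0 + p["b"] * x + p["c"] * x**2))

    alpha = band(lmax, c["alpha"])
    if not template.beta_band:
        return alpha
    beta = c["beta"]["amp"] * band(c["beta"]["lambda"], c["beta"])
    return alpha + beta


def _peak_norm(template: SpectralTemplate) -> tuple[float, float]:
    """(normalization constant, peak wavelength) on the dense internal grid."""
    grid = np.arange(_DENSE_RANGE[0], _DENSE_RANGE[1] + _DENSE_STEP / 2, _DENSE_STEP)
    vals = _raw_template(template, grid)
    i = int(np.argmax(vals))
    return float(vals[i]), float(grid[i])


def evaluate_template(template: SpectralTemplate, wavelengths) -> np.ndarray:
    """Evaluate a peak-normalized template at the given wavelengths (nm).

    The returned vector is normalized so that the maximum of the template
    over a dense 0.1 nm grid spanning 300-700 nm equals 1.
    """
    lam = np.asarray(wavelengths, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("wavelengths must be a non-empty 1-D vector")
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be strictly positive")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelengths must be sorted ascending")
    norm, _ = _peak_norm(template)
    return _raw_template(template, lam) / norm


def template_peak(template: SpectralTemplate) -> tuple[float, bool]:
    """Peak wavelength of the full template on the dense grid.

    Returns ``(peak_nm, beta_dominates)`` where ``beta_dominates`` flags a
    global maximum displaced more than 1 nm from ``lambda_max`` by the
    beta-band superposition.
    """
    _, peak = _peak_norm(template)
    return peak, abs(peak - template.lambda_max) > 1.0


def adjusted_r_squared(observed, predicted, n_params: int) -> float:
    """Adjusted coefficient of determination.

    ``1 - (1 - R^2) * (n - 1) / (n - n_params - 1)``; equals 1 for a
    perfect fit and is penalized for the number of fitted parameters.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    n = y.size
    if n < n_params + 2:
        raise ValueError(f"need at least n_params + 2 = {n_params + 2} points, got {n}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed vector has zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


@dataclass(frozen=True)
class TemplateFit:
    """Result of fitting ``scale * template(lambda; lambda_max)`` to a curve."""

    lambda_max_hat: float
    scale: float
    adjusted_r2: float
    residuals: np.ndarray
    fit_range: tuple[float, float]
    family: str
    beta_band: bool = True
    n_points: int = 0
    success: bool = True
    quality_flag: str = "ok"  # "ok" or "poor_fit" (adjusted R^2 <= 0.8)

    def to_dict(self) -> dict:
        return {
            "lambda_max_hat_nm": round(self.lambda_max_hat, 1),
            "scale": self.scale,
            "adjusted_r2": self.adjusted_r2,
            "fit_range_nm": list(self.fit_range),
            "family": self.family,
            "beta_band": self.beta_band,
            "n_points": self.n_points,
            "success": self.success,
            "quality_flag": self.quality_flag,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _closed_form_scale(t: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.dot(t, t))
    if denom == 0.0:
        return 0.0
    return max(float(np.dot(t, y)) / denom, 0.0)


def _sse_at(lmax, family, beta_band, lam, y, coeffs) -> float:
    tpl = SpectralTemplate(family, float(lmax), beta_band, coeffs)
    t = evaluate_template(tpl, lam)
    s = _closed_form_scale(t, y)
    return float(np.sum((y - s * t) ** 2))


def fit_template(
    wavelengths,
    sensitivities,
    family: str = "stavenga_band",
    fit_range: tuple[float, float] | None = None,
    beta_band: bool = True,
    lambda_max_bounds: tuple[float, float] = (320.0, 650.0),
    band_coefficients: dict | None = None,
) -> TemplateFit:
    """Fit a visual-pigment template to a spectral-sensitivity curve.

    The curve is renormalized to [0, 1] over ``fit_range`` before fitting by
    dividing by its maximum (responses are non-negative, so this maps onto
    [0, 1] while preserving the linear-scale template model; it coincides
    with min-max scaling whenever the minimum response is ~0).  ``lambda_max`` is found by a 1 nm grid pre-scan over
    ``lambda_max_bounds`` followed by bounded local refinement; the linear
    scale is solved in closed form at every candidate ``lambda_max``.

    Accepts either two vectors or a single object with ``wavelengths`` and
    ``mean_sensitivity`` attributes (e.g. ``SpectralSensitivity``) as the
    first argument (pass ``sensitivities=None`` then).
    """
    if sensitivities is None and hasattr(wavelengths, "mean_sensitivity"):
        curve = wavelengths
        wavelengths = curve.wavelengths
        sensitivities = curve.mean_sensitivity
    lam = np.asarray(wavelengths, dtype=float)
    y = np.asarray(sensitivities, dtype=float)
    if lam.shape != y.shape or lam.ndim != 1:
        raise ValueError("wavelengths and sensitivities must be 1-D and equal length")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(lam)):
        raise ValueError("non-finite values in spectral curve")
    if fit_range is None:
        fit_range = (float(lam.min()), float(lam.max()))
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not lo < hi:
        raise ValueError("fit_range must satisfy lo < hi")
    mask = (lam >= lo) & (lam <= hi)
    if int(mask.sum()) < 5:
        raise ValueError("need at least 5 wavelengths inside fit_range")
    lam_f = lam[mask]
    y_f = y[mask]
    if np.any(y_f < 0):
        y_f = y_f - y_f.min()  # tolerate small negative baselines
    if y_f.max() == 0.0 or y_f.max() == y_f.min():
        raise ValueError("sensitivity curve is degenerate over fit_range")
    y_f = y_f / y_f.max()

    coeffs = band_coefficients or TEMPLATE_COEFFICIENTS
    blo, bhi = lambda_max_bounds
    flo, fhi = _FAMILY_RANGE[family] if family in _FAMILY_RANGE else (None, None)
    if flo is None:
        raise ValueError(f"unknown template family: {family!r}")
    blo, bhi = max(blo, flo), min(bhi, fhi)

    grid = np.arange(blo, bhi + 0.5, 1.0)
    sse = np.array([_sse_at(g, family, beta_band, lam_f, y_f, coeffs) for g in grid])
    g0 = grid[int(np.argmin(sse))]
    res = minimize_scalar(
        _sse_at,
        bounds=(max(blo, g0 - 1.5), min(bhi, g0 + 1.5)),
        args=(family, beta_band, lam_f, y_f, coeffs),
        method="bounded",
        options={"xatol": 1e-4},
    )
    success = bool(res.success)
    lmax_hat = float(res.x) if success else float(g0)

    tpl = SpectralTemplate(family, lmax_hat, beta_band, coeffs)
    t = evaluate_template(tpl, lam_f)
    scale = _closed_form_scale(t, y_f)
    pred = scale * t
    adj = adjusted_r_squared(y_f, pred, n_params=2)
    return TemplateFit(
        lambda_max_hat=lmax_hat,
        scale=scale,
        adjusted_r2=adj,
        residuals=y_f - pred,
        fit_range=(lo, hi),
        family=family,
        beta_band=beta_band,
        n_points=int(mask.sum()),
        success=success,
        quality_flag="ok" if adj > 0.8 else "poor_fit",
    )


def lambda_max_shift(wild_type: TemplateFit, mutant: TemplateFit) -> float:
    """Signed spectral shift (mutant minus wild type), rounded to 1 nm.

    Both fits must use the same template family and the same fit range;
    comparing fits made over different testing ranges conflates the
    range-dependence of the estimate with the mutational shift.
    """
    if wild_type.family != mutant.family:
        raise ValueError("fits use different template families")
    if wild_type.fit_range != mutant.fit_range:
        raise ValueError(
            f"fits use different fit ranges: {wild_type.fit_range} vs {mutant.fit_range}"
        )
    return float(round(mutant.lambda_max_hat - wild_type.lambda_max_hat))
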