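"""Fit a visual-pigment template to a spectral-sensitivity curve.

Builds a noisy sensitivity curve for a green-sensitive pigment peaking at
507 nm, fits both template families, and prints the estimated lambda_max
with its goodness of fit.
"""

import numpy as np

from opsintune import SpectralTemplate, evaluate_template, fit_template

rng = np.random.default_rng(0)
wavelengths = np.arange(315.0, 551.0, 5.0)
true_curve = evaluate_template(SpectralTemplate("stavenga_band", 507.0), wavelengths)
measured = np.clip(true_curve + rng.normal(0.0, 0.05, wavelengths.size), 0.0, None)

for family in ("stavenga_band", "govardovskii_a1"):
    fit = fit_template(wavelengths, measured, family=family)
    print(
        f"{family:16s}  lambda_max = {fit.lambda_max_hat:6.1f} nm  "
        f"adjusted R^2 = {fit.adjusted_r2:.3f}  [{fit.quality_flag}]"
    )

# The true peak is 507 nm; both families should land within a few nm of it.
# adjusted R^2 > 0.8 is the quality threshold for trusting the estimate.
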