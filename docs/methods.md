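# Methods

## Visual-pigment templates

A visual pigment's normalized absorbance — and, to good approximation, the
spectral sensitivity of a photoreceptor expressing it — is a near-universal
function of wavelength once the peak wavelength λmax is fixed. Two template
families are implemented, with all coefficients stored in a single
versioned, user-overridable table (`TEMPLATE_COEFFICIENTS`, version 1):

- **`govardovskii_a1`** — the A1 (retinal) nomogram: α band
  `S(x) = 1 / (exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D)` with
  `x = λmax/λ`, `A=69.7, B=28, C=−14.9, D=0.674, b=0.922, c=1.104` and
  `a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940)`, plus a Gaussian β band of
  amplitude 0.26 centred at `189 + 0.315·λmax` with width `−40.5 + 0.195·λmax`.
- **`stavenga_band`** — exponential ("modified Gaussian") bands:
  `exp(−a x²(1 + b x + c x²))` with `x = log10(λ/λband)`; α band
  `a=380, b=6.09, c=26.1` peaking at λmax, β band of amplitude 0.29 fixed at
  350 nm with `a=247, b=3.59`. The minor skew coefficients are the least
  certain entries in the table; they affect only the far limbs of the band,
  and users fitting against a different transcription of the band model can
  supply their own table.

Templates are peak-normalized on an internal 0.1 nm grid over 300–700 nm.
With the β band superposed, the global maximum of a UV template can move a
few nm short of the α-band peak; `template_peak` reports the realized peak
and a `beta_dominates` flag rather than silently renormalizing it away.

### Fitting

`fit_template` minimizes the sum of squared residuals of `scale ·
template(λ; λmax)` against the measured curve over the chosen wavelength
range. λmax is found by a 1 nm grid pre-scan over the configured bounds
(default 320–650 nm) followed by bounded scalar refinement (tolerance
1e-4 nm); the scale is solved in closed form at each candidate λmax, so the
optimization is one-dimensional and deterministic. Goodness of fit is the
adjusted R² with 2 parameters (λmax, scale); fits at or below 0.8 carry a
`poor_fit` quality flag but are never suppressed — a curve that no template
matches (as happens for pigments distorted by screening or expression
artifacts) is still reported, flagged for cautious interpretation.

Before fitting, the curve is renormalized by dividing by its maximum over
the fit range (negative baselines are first shifted to zero). Divide-by-max
rather than min-max scaling preserves the offset-free linear-template model;
the two coincide whenever the minimum response is ≈ 0, which holds for the
measured ranges here, and divide-by-max makes the noiseless round trip
(generate from a template → fit) exact.

Shifts (`lambda_max_shift`) are mutant − wild-type λmax, rounded to 1 nm,
and require identical template family and fit range: the λmax estimate is
range-dependent in the presence of measurement imperfections, so comparing
fits across different testing ranges conflates that dependence with the
mutational effect. Fitting a long-wavelength pigment over a range that
excludes its peak amplifies any calibration error in the data — the reason
pigments measured on two monochromator gratings are compared on the common
315–550 nm range.

## ERG processing

- **Amplitude.** Baseline = mean voltage over the 100 ms (configurable)
  before flash onset; response = baseline minus the minimum voltage in the
  10 ms before flash offset. Positive for the sustained negative
  photoreceptor response; invariant to constant offsets; on/off transients
  fall outside the window. The mean over the last 5 of 10 flashes is used,
  by which point the simulated adaptation has decayed to < 1%.
- **V/log(I).** The Naka–Rushton function is fitted on the log10-intensity
  axis in an overflow-safe logistic form. The "sigmoid" alternative — a
  logistic in log10 I — is mathematically the same two-parameter-shape
  family under reparameterization (`n = 1/(s·ln10)`); both surfaces are
  kept for protocol parity and agree on clean data, with Naka–Rushton
  preferred on ties. Fitting is multi-start (one saturating, one shallow
  start) so that non-saturating data are not trapped at a spuriously
  saturating local optimum. A fit is declared *saturated* when the fitted
  plateau is ≤ 1.2× the largest observed response **and** the fitted curve
  flattens at the top of the tested range (terminal slope ≤ 0.5× the
  maximal slope); the second condition is needed because a logistic fitted
  to strictly log-linear data satisfies the first. Saturated experiments
  use the half-maximum intensity K as the spectral test intensity;
  otherwise the midpoint of the longest log-linear stretch (R² ≥ 0.98 over
  ≥ 3 consecutive points) is used.
- **Equal-response linearization.** A response spectrum measured at one
  fixed intensity is a compressed image of the sensitivity spectrum: with
  the default generator parameters (n = 0.8, test at K) the raw-amplitude
  curve biases λmax by ~6 nm and drops the fit quality below 0.5. The
  analysis therefore defines sensitivity the way the field does — the
  reciprocal of the intensity needed for a criterion response — by
  inverting each animal's fitted V/log(I) function:
  `S(λ) ∝ f⁻¹(V(λ)) / I_test`. `analyze_experiment` and the pipeline apply
  this by default whenever a V/log(I) fit is available;
  `build_sensitivity_curve` used directly keeps raw amplitudes, matching
  the written protocol.
- **Curve building.** Per animal: linearize (optional) → Savitzky–Golay
  smoothing with a window spanning 15 nm of the grid (3 samples at 5 nm
  steps, polynomial order 1 — the only order that smooths with a 3-point
  window; it preserves linear trends exactly) → divide by the series
  maximum. Across animals: mean and standard deviation, then the mean is
  clipped at zero and renormalized to peak 1.
- **Schedule.** Wavelengths are split into three contiguous groups,
  shuffled within groups, and presented cycling low → mid → high, balancing
  slow sensitivity drifts across the spectrum. Deterministic per seed.

## Synthetic data

The generator encodes the model implicit in the measurement: sensitivity
`S(λ)` from a template at the true λmax, response depth
`V = Vmax·(S·I)ⁿ/((S·I)ⁿ+Kⁿ)`. Defaults: Vmax = 12 mV, K = 1e14
photons/cm²/s (mid of the 1.14e12–3.6e16 tested range), n = 0.8, 200 ms
flashes at 1 kHz sampling, ±3 mV raised-cosine on/off transients of 20 ms
(so the amplitude window stays on the plateau and the noiseless pipeline
amplitude equals the analytic depth exactly), 0.1 mV sample noise,
adaptation decaying with an e-fold of 1.5 flashes from +30%, log-normal
per-animal Vmax scatter (σ = 0.2), and Gaussian per-wavelength sensitivity
jitter (σ = 0.05) emulating the spread visible across animals. Experiments
include a per-animal V/log(I) series at the wavelength nearest the peak;
the spectral series runs at the true half-saturating flux.

What the generator does *not* emulate: screening-pigment and self-screening
distortions, chromophore (A1 vs A3) effects, electrode drift, and
cross-grating calibration error. Passing recovery tests therefore show the
*analysis* is unbiased and precise under the stated noise model — not that
real curves are free of those biological distortions; the poor template
fits reported for blue-shifted duplicates in real data are exactly such a
case, and the pipeline's quality flag is the honest output there.

Sequence families plant duplicate-divergent, ortholog-invariant
substitutions at chosen pocket positions, keep decoy pocket sites
invariant, and mutate background positions per species (default 5%) —
the structure the screen is built to detect, with known truth.

## Tuning-site screen

Filters are conjunctive: pocket membership, variant between duplicates in
every species, invariant across species within each copy, structurally
significant substitution. Sites failing only significance are retained with
`candidate=False` so borderline rows remain visible. Classification uses a
fixed property table: polar = {S,T,Y,N,Q,D,E,K,R,H}; hydroxyl = {S,T,Y};
side-chain volumes (Zamyatnin 1972) with a 35 Å³ size-change threshold;
any gain/loss of cysteine flags disulfide-bonding change. Flags are
symmetric, and the label is composed from all raised flags — substitutions
like T/C therefore carry the disulfide flag alongside polarity/hydroxyl,
and S/A carries hydroxyl alongside polarity: the classifier reports every
applicable structural change rather than a single dominant one.

Percent identity uses a global BLOSUM62 alignment (gap open −10, extend
−0.5, EMBOSS-needle-like), scored over alignment columns between the first
and last aligned residue pair (terminal gap runs excluded), rounded to
integer percent. Coordinate mapping walks alignment columns and returns an
explicit gap marker (`None`) when the target lacks the residue; a bovine
rhodopsin reference sequence is bundled for bovine numbering. Pocket
extraction from a structure takes every residue with a heavy atom within
5 Å (configurable) of any heavy atom of the designated ligand.

## Numerical and interface choices

- All randomness flows through `numpy.random.Generator` seeds; generators
  are bit-reproducible, and the pipeline re-run on identical inputs yields
  an identical summary.
- Intensities are handled as log10(photons/cm²/s) inside fits for
  conditioning; reported values are on the linear scale.
- λmax is reported to 1 nm; shifts are rounded to 1 nm (banker's rounding,
  which keeps shift antisymmetry exact).
- Tabular outputs carry a comment header with the package version and a
  hash of the resolved configuration; unknown configuration keys are
  rejected at load time.
- Problem sizes in the test suite and acceptance script (6 animals per
  wild-type curve, 4 per mutant, 48–51 wavelengths, 50–100 Monte-Carlo
  replicates) match the scale of the emulated experiments.

## Known limitations

- The template coefficient table is a transcription of the two published
  band models; the skew terms of the exponential-band family are the least
  certain (see above) and the table is versioned for that reason.
- The screen's significance rules are a calibrated approximation of
  structural-change reasoning; they reproduce the classifications they were
  built against but are not a substitute for structural modeling.
- Percent identity depends mildly on alignment gap costs for highly
  diverged pairs; a pre-computed alignment can be supplied to bypass the
  built-in aligner.
- No chromophore (A1↔A3) conversion model, no photoreceptor optics
  (screening, self-screening), no structure prediction.
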