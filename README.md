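# opsintune

Spectral characterization of visual pigments from electroretinogram (ERG)
recordings, and screening of opsin gene duplicates for candidate
spectral-tuning sites.

## Who this is for

Visual physiologists and molecular evolution researchers who express opsins
heterologously (for example in *Drosophila* photoreceptors) and need a
reproducible path from raw flash recordings to a peak sensitivity estimate
— and who then want to ask *which* amino-acid substitutions between opsin
duplicates could explain a measured spectral shift.

## What it computes

**From ERG traces to λmax.** The response to a monochromatic flash is the
voltage drop from the pre-flash baseline to the minimum in the last 10 ms of
the flash; the mean over the final five flashes of a train is the response
for that stimulus. An intensity series at the pigment's approximate peak is
fitted with the Naka–Rushton function

    V = Vmax · Iⁿ / (Iⁿ + Kⁿ)

whose half-saturating intensity *K* sets the test intensity for the
wavelength series (315–550 or 450–700 nm in 5 nm steps, semi-randomized).
Per-animal response spectra are converted to equal-response sensitivities
through the inverse of the fitted V/log(I) function, smoothed
(Savitzky–Golay, 15 nm window), normalized, and averaged. A visual-pigment
template — either a Govardovskii-type A1 nomogram or a Stavenga-type
exponential band model, each with an optional β band — is then fitted with
two free parameters (λmax and a linear scale), reporting an adjusted R².
Wild-type vs. mutant shifts are differences of λmax estimates made over the
same wavelength range.

**Tuning-site screen.** Candidate spectral-tuning sites in opsin duplicates
are pocket residues (user-supplied list, or residues within 5 Å of the
chromophore in a PDB structure) that are variant between duplicates in every
screened species, invariant across species within each duplicate, and whose
substitution changes side-chain polarity, hydroxyl group, volume, or
disulfide-bonding capacity. Positions are reported in reference and bovine
rhodopsin numbering, and global-alignment percent identity between any two
opsins is available.

**Synthetic data.** `opsintune.simulate` generates complete ERG experiments
(template sensitivity × Naka–Rushton nonlinearity, on/off transients,
adaptation, per-animal variability, Gaussian noise) with a ground-truth
manifest, and opsin sequence families with planted pocket substitutions —
so every stage of the pipeline is testable without any recordings.

## Worked example

```python
from opsintune import (PhotoreceptorModel, SpectralTemplate,
                       analyze_experiment, simulate_experiment)

model = PhotoreceptorModel(template=SpectralTemplate("stavenga_band", 507.0))
experiment = simulate_experiment(model, n_animals=6, seed=42, level="trace")
curve, fit, vlogi_fits, _ = analyze_experiment(
    series_by_animal=experiment.series, vlogi_by_animal=experiment.vlogi)
print(fit.lambda_max_hat, fit.adjusted_r2)
```

prints

```
estimated lambda_max  = 507.0 nm
adjusted R^2          = 0.997
```

(`examples/03_erg_experiment.py`): six simulated animals expressing a
507 nm pigment are analyzed end to end, and the template fit recovers the
generator's peak to within a fraction of a nanometre with a near-perfect
fit quality. The other scripts in `examples/` each demonstrate one
capability: template fitting, V/log(I) fitting, mutant shifts, and the
tuning-site screen.

A thin CLI wraps the same stages:

```sh
opsintune simulate --lambda-max 507 --out demo/
opsintune curve --traces demo/traces.csv --vlogi demo/vlogi.csv --out demo/curve.tsv
opsintune fit --curve demo/curve.tsv --out demo/fit.json
```

## Layout

- `src/opsintune/templates.py` — template evaluation and λmax fitting
- `src/opsintune/erg.py` — amplitudes, V/log(I), curves, schedules
- `src/opsintune/screen.py` — identity, site mapping, classification, pocket, screen
- `src/opsintune/simulate.py` — synthetic experiments and sequence families
- `src/opsintune/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
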