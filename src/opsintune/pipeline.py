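"""End-to-end orchestration: raw recordings to a machine-readable report.

``run_pipeline`` chains the stages the measurement protocol defines —
flash amplitudes, V/log(I) fits, sensitivity-curve construction, template
fitting, mutant shift, and the tuning-site screen — skipping stages whose
inputs are absent, and writes every intermediate table plus a summary JSON
and the resolved configuration into the output directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .erg import build_sensitivity_curve, fit_vlogi, series_response
from .screen import pocket_sites_from_structure, screen_candidates
from .templates import fit_template, lambda_max_shift

__all__ = ["StageError", "run_pipeline", "analyze_experiment"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[stage: {stage}] {detail}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


def analyze_experiment(
    series_by_animal: dict | None = None,
    vlogi_by_animal: dict | None = None,
    amplitudes_by_animal: dict | None = None,
    n_last: int = 5,
    baseline_ms: float = 100.0,
    window_ms: float = 10.0,
    smoothing_window_nm: float = 15.0,
    linearize: bool = True,
    vlogi_model: str = "naka_rushton",
    family: str = "stavenga_band",
    beta_band: bool = True,
    fit_range: tuple | None = None,
    lambda_max_bounds: tuple = (320.0, 650.0),
):
    """Library-level end-to-end analysis of one opsin's ERG experiment.

    Takes either trace-level data (``series_by_animal``: animal ->
    {wavelength: FlashSeries}) or precomputed amplitude tables
    (``amplitudes_by_animal``: animal -> (wavelengths, responses)).  When
    V/log(I) series are supplied, responses are converted to equal-response
    sensitivities through each animal's fitted intensity-response function
    before smoothing and averaging (``linearize=False`` keeps raw
    amplitudes).  Returns ``(curve, template_fit, vlogi_fits, amplitudes)``.
    """
    if series_by_animal is None and amplitudes_by_animal is None:
        raise ValueError("need trace series or amplitude tables")
    if amplitudes_by_animal is None:
        amplitudes_by_animal = {}
        for aid, by_lam in series_by_animal.items():
            lams = np.array(sorted(by_lam))
            resp = np.array(
                [
                    series_response(
                        by_lam[lam], n_last=n_last,
                        baseline_ms=baseline_ms, window_ms=window_ms,
                    )
                    for lam in lams
                ]
            )
            amplitudes_by_animal[aid] = (lams, resp)

    vlogi_fits = None
    fits_by_animal = {}
    if vlogi_by_animal is not None:
        fits_by_animal = {
            aid: fit_vlogi(I, V, model=vlogi_model)
            for aid, (I, V) in vlogi_by_animal.items()
        }
    animal_ids = sorted(amplitudes_by_animal)
    if linearize and fits_by_animal:
        if set(animal_ids) <= set(fits_by_animal):
            vlogi_fits = [fits_by_animal[a] for a in animal_ids]
        elif len(fits_by_animal) == 1:
            vlogi_fits = [next(iter(fits_by_animal.values()))] * len(animal_ids)
        else:
            raise ValueError("V/logI fits do not cover the animals in the spectral data")

    per_animal = [amplitudes_by_animal[a] for a in animal_ids]
    curve = build_sensitivity_curve(
        per_animal, window_nm=smoothing_window_nm, vlogi_fits=vlogi_fits
    )
    tfit = fit_template(
        curve,
        None,
        family=family,
        beta_band=beta_band,
        fit_range=fit_range,
        lambda_max_bounds=lambda_max_bounds,
    )
    return curve, tfit, fits_by_animal, amplitudes_by_animal


def run_pipeline(config) -> dict:
    """Run every stage enabled by the configuration; returns the summary dict.

    Outputs written to ``config.paths['outdir']``: resolved config YAML,
    per-animal amplitude TSV, V/log(I) fit JSON, sensitivity curve TSV,
    template-fit JSON, shift table, screen TSV, and ``summary.json``.
    """
    import yaml

    if isinstance(config, (str, Path)):
        config = oio.load_config(config)
    outdir = Path(config.paths["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    summary: dict = {"config_hash": h, "stages": []}

    (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(config.to_dict()))

    p = config.paths
    for key in ("traces_csv", "vlogi_csv", "curve_tsv", "mutant_curve_tsv",
                "sequences_fasta", "pocket_tsv", "structure_pdb"):
        if p[key] is not None and not Path(p[key]).exists():
            raise StageError("inputs", f"configured input does not exist: {key}={p[key]}")

    series_by_animal = None
    if p["traces_csv"]:
        series_by_animal = _read_traces(p["traces_csv"])
        summary["stages"].append("amplitudes")
    vlogi_by_animal = _read_vlogi(p["vlogi_csv"]) if p["vlogi_csv"] else None
    if vlogi_by_animal is not None:
        summary["stages"].append("vlogi")

    a = config.analysis
    curve = tfit = None
    if series_by_animal is not None:
        curve, tfit, vfits, amps = _analyze(config, series_by_animal, vlogi_by_animal)
        amp_rows = []
        for aid, (lams, resp) in amps.items():
            for lam, r in zip(lams, resp):
                amp_rows.append(
                    {"animal_id": aid, "wavelength_nm": lam, "response_mV": r}
                )
        oio._write_table(pd.DataFrame(amp_rows), outdir / "amplitudes.tsv", "\t", h)
        if vfits:
            oio.write_json(
                {aid: f.to_dict() for aid, f in vfits.items()},
                outdir / "vlogi_fits.json",
            )
            summary["vlogi"] = {aid: f.to_dict() for aid, f in vfits.items()}
        oio.write_curve_tsv(curve, outdir / "sensitivity_curve.tsv", h)
        summary["stages"] += ["curve", "fit"]
    elif p["curve_tsv"]:
        curve = _read_curve(p["curve_tsv"])
        tfit = _fit_curve(config, curve)
        summary["stages"].append("fit")

    if tfit is not None:
        oio.write_json(tfit.to_dict(), outdir / "template_fit.json")
        summary["template_fit"] = tfit.to_dict()

    if p["mutant_curve_tsv"]:
        if tfit is None:
            raise StageError("shift", "mutant curve given but no wild-type fit available")
        mcurve = _read_curve(p["mutant_curve_tsv"])
        mfit = _fit_curve(config, mcurve, fit_range=tfit.fit_range)
        shift = lambda_max_shift(tfit, mfit)
        summary["mutant_fit"] = mfit.to_dict()
        summary["lambda_max_shift_nm"] = shift
        oio.write_json(
            {"wild_type": tfit.to_dict(), "mutant": mfit.to_dict(), "shift_nm": shift},
            outdir / "shift.json",
        )
        summary["stages"].append("shift")

    if p["sequences_fasta"]:
        records = _screen(config)
        oio.write_screen_tsv(records, outdir / "screen.tsv", h)
        summary["screen"] = {
            "n_sites": len(records),
            "candidates": [r.site.position_ref for r in records if r.candidate],
        }
        summary["stages"].append("screen")

    oio.write_json(summary, outdir / "summary.json")
    return summary


@_stage("amplitudes")
def _read_traces(path):
    return oio.read_traces_csv(path)


@_stage("vlogi")
def _read_vlogi(path):
    return oio.read_vlogi_csv(path)


@_stage("curve")
def _read_curve(path):
    return oio.read_curve_tsv(path)


@_stage("fit")
def _fit_curve(config, curve, fit_range=None):
    a = config.analysis
    return fit_template(
        curve,
        None,
        family=a["template_family"],
        beta_band=a["beta_band"],
        fit_range=fit_range or (tuple(a["fit_range"]) if a["fit_range"] else None),
        lambda_max_bounds=tuple(a["lambda_max_bounds"]),
    )


@_stage("curve")
def _analyze(config, series_by_animal, vlogi_by_animal):
    a, pr = config.analysis, config.protocol
    return analyze_experiment(
        series_by_animal=series_by_animal,
        vlogi_by_animal=vlogi_by_animal,
        n_last=pr["n_last"],
        baseline_ms=pr["baseline_ms"],
        window_ms=pr["window_ms"],
        smoothing_window_nm=a["smoothing_window_nm"],
        linearize=a["linearize"],
        vlogi_model=a["vlogi_model"],
        family=a["template_family"],
        beta_band=a["beta_band"],
        fit_range=tuple(a["fit_range"]) if a["fit_range"] else None,
        lambda_max_bounds=tuple(a["lambda_max_bounds"]),
    )


@_stage("screen")
def _screen(config):
    p, s = config.paths, config.screen
    opsins = oio.read_fasta(p["sequences_fasta"], as_opsin_set=True)
    if opsins.alignment is None:
        lengths = {len(v) for v in opsins.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(
                "sequences are unaligned and of unequal length; provide an "
                "aligned FASTA (gapped) instead"
            )
        opsins.alignment = dict(opsins.sequences)
    if p["pocket_tsv"]:
        pocket = oio.read_pocket_tsv(p["pocket_tsv"])
    elif p["structure_pdb"]:
        pocket = pocket_sites_from_structure(
            p["structure_pdb"],
            ligand_resname=s["ligand_resname"],
            cutoff=s["cutoff_A"],
        )
    else:
        raise ValueError("screen needs pocket_tsv or structure_pdb")
    ref = tuple(s["reference_key"]) if s["reference_key"] else None
    return screen_candidates(opsins, pocket, reference_key=ref)
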