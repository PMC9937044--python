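"""Readers, writers and pipeline configuration.

Tabular data move as TSV/CSV through pandas, sequences as FASTA through
Bio.SeqIO, structures as PDB, fits and manifests as JSON, configuration as
YAML.  Every tabular writer prepends a commented header recording the
package version and the configuration hash so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .erg import ERGTrace, FlashSeries, SpectralSensitivity
from .screen import OpsinSet, PocketSite

__all__ = [
    "PipelineConfig",
    "read_curve_tsv",
    "write_curve_tsv",
    "read_traces_csv",
    "write_traces_csv",
    "read_vlogi_csv",
    "write_vlogi_csv",
    "read_fasta",
    "write_fasta",
    "read_pocket_tsv",
    "write_pocket_tsv",
    "write_screen_tsv",
    "write_json",
    "load_config",
]

TRACE_COLUMNS = ["animal_id", "wavelength_nm", "flux", "flash_index", "time_s", "voltage_mV"]


def _header(config_hash: str | None) -> str:
    h = config_hash or "none"
    return f"# opsintune v{__version__} config_hash={h}\n"


def _read_table(path, sep):
    return pd.read_csv(path, sep=sep, comment="#")


def _write_table(df: pd.DataFrame, path, sep, config_hash=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------- curves

def write_curve_tsv(curve: SpectralSensitivity, path, config_hash=None):
    df = pd.DataFrame(
        {
            "wavelength_nm": curve.wavelengths,
            "sensitivity": curve.mean_sensitivity,
            "sd": curve.sd,
            "n": curve.n_animals,
        }
    )
    _write_table(df, path, "\t", config_hash)


def read_curve_tsv(path) -> SpectralSensitivity:
    df = _read_table(path, "\t")
    if "wavelength_nm" not in df or "sensitivity" not in df:
        raise ValueError(f"{path}: expected columns wavelength_nm, sensitivity")
    sd = df["sd"].to_numpy() if "sd" in df else np.zeros(len(df))
    n = int(df["n"].iloc[0]) if "n" in df else 1
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    return SpectralSensitivity(
        wavelengths=lam,
        mean_sensitivity=df["sensitivity"].to_numpy(dtype=float),
        sd=sd,
        n_animals=n,
        testing_range=(float(lam.min()), float(lam.max())),
    )


# ---------------------------------------------------------------- traces

def write_traces_csv(series_by_animal: dict, path, config_hash=None):
    """``series_by_animal``: animal_id -> {wavelength: FlashSeries}."""
    frames = []
    for aid, by_lam in series_by_animal.items():
        for lam, series in by_lam.items():
            for k, tr in enumerate(series.traces):
                frames.append(
                    pd.DataFrame(
                        {
                            "animal_id": aid,
                            "wavelength_nm": lam,
                            "flux": tr.photon_flux,
                            "flash_index": k,
                            "time_s": tr.time,
                            "voltage_mV": tr.voltage,
                            "flash_onset_s": tr.flash_onset,
                            "flash_offset_s": tr.flash_offset,
                        }
                    )
                )
    _write_table(pd.concat(frames, ignore_index=True), path, ",", config_hash)


def read_traces_csv(path) -> dict:
    """Long-format trace CSV -> animal_id -> {wavelength: FlashSeries}."""
    df = _read_table(path, ",")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict = {}
    for (aid, lam, flux), g in df.groupby(["animal_id", "wavelength_nm", "flux"], sort=True):
        traces = []
        for _, gg in g.groupby("flash_index", sort=True):
            onset = float(gg["flash_onset_s"].iloc[0]) if "flash_onset_s" in gg else 0.2
            offset = float(gg["flash_offset_s"].iloc[0]) if "flash_offset_s" in gg else 0.4
            traces.append(
                ERGTrace(
                    time=gg["time_s"].to_numpy(dtype=float),
                    voltage=gg["voltage_mV"].to_numpy(dtype=float),
                    flash_onset=onset,
                    flash_offset=offset,
                    wavelength=float(lam),
                    photon_flux=float(flux),
                )
            )
        out.setdefault(aid, {})[float(lam)] = FlashSeries(traces)
    return out


# ---------------------------------------------------------------- V/log(I)

def write_vlogi_csv(vlogi_by_animal: dict, path, config_hash=None):
    """``vlogi_by_animal``: animal_id -> (intensities, responses)."""
    rows = []
    for aid, (I, V) in vlogi_by_animal.items():
        for i, v in zip(I, V):
            rows.append({"animal_id": aid, "intensity": i, "response_mV": v})
    _write_table(pd.DataFrame(rows), path, ",", config_hash)


def read_vlogi_csv(path) -> dict:
    df = _read_table(path, ",")
    for c in ("animal_id", "intensity", "response_mV"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    out = {}
    for aid, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("intensity")
        out[aid] = (
            g["intensity"].to_numpy(dtype=float),
            g["response_mV"].to_numpy(dtype=float),
        )
    return out


# ---------------------------------------------------------------- sequences

def _parse_key(name: str):
    """FASTA id '<species>|<copy>' -> key tuple; plain ids stay strings."""
    if "|" in name:
        sp, cp = name.split("|", 1)
        return (sp, cp)
    return name


def read_fasta(path, as_opsin_set: bool = False):
    records = {
        _parse_key(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if not as_opsin_set:
        return records
    gapped = any("-" in s for s in records.values())
    if gapped:
        seqs = {k: s.replace("-", "") for k, s in records.items()}
        return OpsinSet(sequences=seqs, alignment=records)
    return OpsinSet(sequences=records)


def write_fasta(sequences: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = []
    for key, seq in sequences.items():
        name = "|".join(key) if isinstance(key, tuple) else str(key)
        recs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- pocket / screen

def read_pocket_tsv(path) -> list:
    df = _read_table(path, "\t")
    if "position_ref" not in df.columns:
        raise ValueError(f"{path}: missing column position_ref")
    sites = []
    for _, row in df.iterrows():
        bov = row.get("position_bovine")
        sites.append(
            PocketSite(
                position_ref=int(row["position_ref"]),
                position_bovine=None if pd.isna(bov) else int(bov),
                source=str(row.get("source", "predicted_pocket")),
            )
        )
    return sites


def write_pocket_tsv(sites: list, path, config_hash=None):
    df = pd.DataFrame(
        {
            "position_ref": [s.position_ref for s in sites],
            "position_bovine": [s.position_bovine for s in sites],
            "source": [s.source for s in sites],
        }
    )
    _write_table(df, path, "\t", config_hash)


def write_screen_tsv(records: list, path, config_hash=None):
    rows = []
    for r in records:
        row = {
            "position_ref": r.site.position_ref,
            "position_bovine": r.site.position_bovine,
            "source": r.site.source,
            "candidate": r.candidate,
            "significant": r.classification.significant,
            "classification": r.classification.label,
        }
        for (sp, cp), aa in r.residues_by_key.items():
            row[f"{sp}|{cp}"] = aa
        for sp, v in r.variant_between_duplicates.items():
            row[f"variant[{sp}]"] = v
        for cp, v in r.invariant_across_species.items():
            row[f"invariant[{cp}]"] = v
        rows.append(row)
    _write_table(pd.DataFrame(rows), path, "\t", config_hash)


def write_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


# ---------------------------------------------------------------- config

_PROTOCOL_KEYS = {
    "flash_ms": 200.0,
    "interflash_s": 5.0,
    "n_flashes": 10,
    "n_last": 5,
    "baseline_ms": 100.0,
    "window_ms": 10.0,
}
_ANALYSIS_KEYS = {
    "smoothing_window_nm": 15.0,
    "template_family": "stavenga_band",
    "beta_band": True,
    "fit_range": None,  # defaults to the testing range
    "lambda_max_bounds": (320.0, 650.0),
    "linearize": True,
    "vlogi_model": "naka_rushton",
}
_SCREEN_KEYS = {
    "reference_key": None,
    "ligand_resname": None,
    "cutoff_A": 5.0,
}
_PATH_KEYS = {
    "traces_csv": None,
    "vlogi_csv": None,
    "curve_tsv": None,
    "mutant_curve_tsv": None,
    "sequences_fasta": None,
    "pocket_tsv": None,
    "structure_pdb": None,
    "outdir": "opsintune_out",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    paths: dict = field(default_factory=lambda: dict(_PATH_KEYS))
    protocol: dict = field(default_factory=lambda: dict(_PROTOCOL_KEYS))
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_KEYS))
    screen: dict = field(default_factory=lambda: dict(_SCREEN_KEYS))
    seed: int = 0

    def __post_init__(self):
        for name, defaults in (
            ("paths", _PATH_KEYS),
            ("protocol", _PROTOCOL_KEYS),
            ("analysis", _ANALYSIS_KEYS),
            ("screen", _SCREEN_KEYS),
        ):
            given = getattr(self, name)
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown config keys in '{name}': {sorted(unknown)}")
            merged = dict(defaults)
            merged.update(given)
            setattr(self, name, merged)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {"paths", "protocol", "analysis", "screen", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        for sect in ("paths", "protocol", "analysis", "screen"):
            d[sect] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d[sect].items()
            }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(data)
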