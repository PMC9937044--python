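"""Shared fixtures: synthetic stand-in curves, toy structures, toy families.

All data here are generated programmatically.  Where a fixture emulates a
published object that cannot be bundled (mean sensitivity curves, deposited
opsin sequences), it is a synthetic stand-in built from the package's own
generator at the published study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from opsintune import (
    PhotoreceptorModel,
    SpectralTemplate,
    analyze_experiment,
    simulate_experiment,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def standin_mean_curve(
    lambda_max: float,
    seed: int,
    n_animals: int = 6,
    testing_range: tuple = (315.0, 550.0),
    noise_sd: float = 0.05,
    family: str = "stavenga_band",
):
    """Synthetic stand-in for a published mean sensitivity curve.

    Simulates a full amplitude-level ERG experiment for a photoreceptor whose
    true peak is ``lambda_max`` and runs the standard analysis (V/logI fits,
    equal-response linearization, smoothing, averaging).  Returns the final
    :class:`SpectralSensitivity` curve.
    """
    model = PhotoreceptorModel(template=SpectralTemplate(family, lambda_max))
    exp = simulate_experiment(
        model,
        n_animals=n_animals,
        testing_range=testing_range,
        seed=seed,
        sensitivity_noise_sd=noise_sd,
        level="amplitude",
    )
    curve, _, _, _ = analyze_experiment(
        amplitudes_by_animal={k: (v["wavelengths"], v["responses"])
                              for k, v in exp.amplitudes.items()},
        vlogi_by_animal=exp.vlogi,
        family=family,
    )
    return curve


def toy_pdb(residue_atoms, ligand_atoms, ligand_resname: str = "RET") -> str:
    """Minimal PDB text: CA-only protein residues plus a heteroatom ligand.

    ``residue_atoms``: list of (x, y, z) per residue (residue numbers 1..n);
    ``ligand_atoms``: list of (x, y, z) for the chromophore.
    """
    lines = []
    serial = 1
    for i, (x, y, z) in enumerate(residue_atoms, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    for j, (x, y, z) in enumerate(ligand_atoms, start=1):
        lines.append(
            f"HETATM{serial:5d}  C{j:<2d} {ligand_resname} A{900:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_table1_family(seed: int = 7, length: int = 340):
    """Synthetic opsin families emulating the published candidate-site table.

    Builds UV and LW duplicate pairs for two focal species plus one outgroup
    species, planting the seven published pocket-site substitutions with the
    published variation pattern: five UV sites (130 S/T, 198 A/Q, 217 I/L,
    285 Y/F, 316 S/A) and two LW sites (140 T/C, 227 C/V).  Site 316 is made
    variant across species within copy 1 (it was variable only within the
    focal genus in the published data), so the cross-species invariance
    filter removes it.  Returns ``(uv_set, uv_sites, lw_set, lw_sites)``.
    """
    from opsintune import OpsinSet

    rng = np.random.default_rng(seed)
    aas = np.array(list(AA))

    def family(planted, copies, outgroup_override=None):
        base = rng.choice(aas, size=length)
        seqs = {}
        for sp in ("rajah", "mniszechii", "outgroup"):
            seq = base.copy()
            # background divergence outside planted sites
            protected = {p for p, _, _ in planted}
            rate = 0.02 if sp != "outgroup" else 0.10
            for pos in range(1, length + 1):
                if pos in protected:
                    continue
                if rng.random() < rate:
                    seq[pos - 1] = rng.choice(aas[aas != seq[pos - 1]])
            for copy_i, label in enumerate(copies):
                cseq = seq.copy()
                for pos, a1, a2 in planted:
                    cseq[pos - 1] = a1 if copy_i == 0 else a2
                if outgroup_override and sp == "outgroup":
                    for pos, label_ov, aa in outgroup_override:
                        if label == label_ov:
                            cseq[pos - 1] = aa
                seqs[(sp, label)] = "".join(cseq)
        return OpsinSet(sequences=seqs, alignment=dict(seqs))

    uv_planted = [
        (130, "S", "T"),
        (198, "A", "Q"),
        (217, "I", "L"),
        (285, "Y", "F"),
        (316, "S", "A"),
    ]
    # outgroup carries A at 316 in copy 1 as well -> copy 1 not invariant
    uv = family(uv_planted, ("UV1", "UV2"), outgroup_override=[(316, "UV1", "A")])
    lw_planted = [(140, "T", "C"), (227, "C", "V")]
    lw = family(lw_planted, ("LW1", "LW2"))
    return uv, [p for p, _, _ in uv_planted], lw, [p for p, _, _ in lw_planted]


@pytest.fixture(scope="session")
def table1_family():
    return make_table1_family()
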