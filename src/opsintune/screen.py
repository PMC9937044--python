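"""Screening opsin duplicates for candidate spectral-tuning sites.

Spectral tuning works through residues that alter the electrostatic
environment of the chromophore, so candidate sites are screened with
conjunctive filters: (1) the site lies in the chromophore binding pocket
(user-supplied list, or every residue with a heavy atom within 5 A of the
chromophore in a structure); (2) it is variant between the two opsin
duplicates in every screened species; (3) it is invariant across species
within each duplicate (so the substitution tracks the duplication, not the
speciation); and (4) the substitution is predicted to be structurally
significant - a change in side-chain polarity, hydroxyl group, volume, or
disulfide-bonding capacity.

Residue positions are reported both in the coordinates of a chosen
reference sequence and mapped through an alignment onto bovine rhodopsin
numbering, the field's common frame of reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "OpsinSet",
    "PocketSite",
    "SubstitutionClass",
    "SiteRecord",
    "BOVINE_RHODOPSIN",
    "AA_VOLUME",
    "POLAR",
    "HYDROXYL",
    "pairwise_identity",
    "align_pair",
    "map_site",
    "classify_substitution",
    "pocket_sites_from_structure",
    "screen_candidates",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_AA = STANDARD_AA | {"X"}

#: Bovine rhodopsin (UniProt P02699) used as the numbering reference.
BOVINE_RHODOPSIN = (
    "MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLYVTVQHKKLRTPLNYILLN"
    "LAVADLFMVFGGFTTTLYTSLHGYFVFGPTGCNLEGFFATLGGEIALWSLVVLAIERYVVVCKPMSNFRFGENHAIMG"
    "VAFTWVMALACAAPPLVGWSRYIPEGMQCSCGIDYYTPHEETNNESFVIYMFVVHFIIPLIVIFFCYGQLVFTVKEAA"
    "AQQQESATTQKAEKEVTRMVIIMVIAFLICWLPYAGVAFYIFTHQGSDFGPIFMTIPAFFAKTSAVYNPVIYIMMNKQ"
    "FRNCMVTTLCCGKNPLGDDEASTTVSKTETSQVAPA"
)

#: Polar side chains (Ser/Thr/Tyr counted polar through their hydroxyl).
POLAR = set("STYNQDEKRH")
#: Hydroxyl-bearing side chains (the "-OH rule" residues).
HYDROXYL = set("STY")
#: Side-chain volumes in cubic Angstrom (Zamyatnin 1972 consensus values).
AA_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
#: Volume difference (A^3) beyond which a substitution counts as a size change.
SIZE_THRESHOLD = 35.0


def _check_protein(seq: str, allow_x: bool = True) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    allowed = EXTENDED_AA if allow_x else STANDARD_AA
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return seq


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine gaps); returns gapped rows."""
    seq_a, seq_b = _check_protein(seq_a), _check_protein(seq_b)
    aln = _aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(seq_a: str, seq_b: str) -> int:
    """Percent identity from a global alignment, to the nearest integer.

    Identity = matching columns / alignment columns, excluding columns that
    lie in terminal gap runs (so a short fragment aligned to a full-length
    sequence is scored over the overlapping region only).
    """
    a, b = align_pair(seq_a, seq_b)
    cols = np.array([(ca, cb) for ca, cb in zip(a, b)])
    non_gap = (cols[:, 0] != "-") & (cols[:, 1] != "-")
    # trim terminal-gap columns: region between first and last position where
    # both rows have residues
    idx = np.flatnonzero(non_gap)
    lo, hi = idx[0], idx[-1] + 1
    a_core, b_core = a[lo:hi], b[lo:hi]
    matches = sum(ca == cb and ca != "-" for ca, cb in zip(a_core, b_core))
    return int(round(100.0 * matches / len(a_core)))


@dataclass
class OpsinSet:
    """Opsin sequences keyed by (species, copy label), optionally aligned."""

    sequences: dict
    alignment: dict | None = None

    def __post_init__(self):
        for key, seq in self.sequences.items():
            self.sequences[key] = _check_protein(seq)
        if self.alignment is not None:
            if set(self.alignment) != set(self.sequences):
                raise ValueError("alignment keys must match sequence keys")
            lengths = {len(row) for row in self.alignment.values()}
            if len(lengths) != 1:
                raise ValueError("alignment rows must have equal length")
            for key, row in self.alignment.items():
                if row.replace("-", "").upper() != self.sequences[key]:
                    raise ValueError(f"alignment row for {key} does not degap to its sequence")

    @property
    def species(self) -> list:
        return sorted({k[0] for k in self.sequences})

    @property
    def copies(self) -> list:
        return sorted({k[1] for k in self.sequences})


@dataclass(frozen=True)
class PocketSite:
    """A chromophore-pocket residue in reference (and bovine) numbering."""

    position_ref: int
    position_bovine: int | None = None
    source: str = "predicted_pocket"  # or "within_5A"


@dataclass(frozen=True)
class SubstitutionClass:
    """Physicochemical classification of one residue substitution."""

    residues: tuple
    polarity_change: bool
    hydroxyl_change: bool
    size_change: bool
    disulfide_change: bool

    @property
    def significant(self) -> bool:
        return (
            self.polarity_change
            or self.hydroxyl_change
            or self.size_change
            or self.disulfide_change
        )

    @property
    def label(self) -> str:
        parts = []
        if self.polarity_change:
            parts.append("polarity")
        if self.hydroxyl_change:
            parts.append("hydroxyl group")
        if self.size_change:
            parts.append("size")
        if self.disulfide_change:
            parts.append("disulfide bonding")
        if not parts:
            return "Most likely insignificant"
        return "Change in " + " and ".join(parts)


def classify_substitution(aa1: str, aa2: str) -> SubstitutionClass:
    """Classify a substitution by polarity, hydroxyl, size and disulfide flags.

    Symmetric in its arguments; identical residues carry no flags.
    """
    aa1, aa2 = aa1.upper(), aa2.upper()
    for aa in (aa1, aa2):
        if aa not in STANDARD_AA:
            raise ValueError(f"nonstandard residue: {aa!r}")
    if aa1 == aa2:
        return SubstitutionClass((aa1, aa2), False, False, False, False)
    return SubstitutionClass(
        residues=(aa1, aa2),
        polarity_change=(aa1 in POLAR) != (aa2 in POLAR),
        hydroxyl_change=(aa1 in HYDROXYL) != (aa2 in HYDROXYL),
        size_change=abs(AA_VOLUME[aa1] - AA_VOLUME[aa2]) > SIZE_THRESHOLD,
        disulfide_change=(aa1 == "C") != (aa2 == "C"),
    )


def map_site(alignment: dict, from_key, to_key, position: int):
    """Map a 1-based residue position between sequences through an alignment.

    Returns the 1-based position in the target sequence at the alignment
    column of the query residue, or ``None`` when the target has a gap in
    that column.
    """
    if from_key not in alignment or to_key not in alignment:
        missing = [k for k in (from_key, to_key) if k not in alignment]
        raise KeyError(f"key(s) absent from alignment: {missing}")
    row_from, row_to = alignment[from_key], alignment[to_key]
    if len(row_from) != len(row_to):
        raise ValueError("alignment rows differ in length")
    n_res = len(row_from) - row_from.count("-")
    if not (1 <= position <= n_res):
        raise ValueError(f"position {position} beyond sequence length {n_res}")
    count = 0
    for col, ch in enumerate(row_from):
        if ch != "-":
            count += 1
            if count == position:
                if row_to[col] == "-":
                    return None
                return len(row_to[: col + 1]) - row_to[: col + 1].count("-")
    raise AssertionError("unreachable")


def pocket_sites_from_structure(
    structure_path,
    ligand_resname: str | None = None,
    cutoff: float = 5.0,
    model_index: int = 0,
) -> list:
    """Chromophore-pocket residues from an atomic structure.

    A residue belongs to the pocket when any of its heavy atoms lies within
    ``cutoff`` Angstrom of any heavy atom of the ligand (the chromophore).
    The ligand is the heteroresidue named ``ligand_resname``, or the single
    non-water heteroresidue if a name is not given.  Returns
    :class:`PocketSite` records (``position_ref`` = residue number) sorted
    by residue number; deterministic.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", structure_path)
    model = list(structure)[model_index]

    ligand_atoms, protein = [], []
    for chain in model:
        for res in chain:
            het = res.id[0].strip()
            if het and het != "W":
                if ligand_resname is None or res.get_resname() == ligand_resname:
                    ligand_atoms.extend(
                        a for a in res if a.element != "H"
                    )
            elif not het:
                protein.append(res)
    if not ligand_atoms:
        raise ValueError("no ligand found in structure")
    if not protein:
        raise ValueError("structure contains no protein residues")
    lig_xyz = np.array([a.coord for a in ligand_atoms], dtype=float)

    sites = []
    for res in protein:
        xyz = np.array([a.coord for a in res if a.element != "H"], dtype=float)
        if xyz.size == 0:
            continue
        d2 = ((xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
        if cutoff > 0 and d2.min() <= cutoff**2:
            sites.append(PocketSite(position_ref=res.id[1], source="within_5A"))
    return sorted(sites, key=lambda s: s.position_ref)


@dataclass
class SiteRecord:
    """One pocket site evaluated across duplicates and species."""

    site: PocketSite
    residues_by_key: dict
    variant_between_duplicates: dict  # species -> bool
    invariant_across_species: dict  # copy -> bool
    classification: SubstitutionClass
    candidate: bool


def screen_candidates(
    opsins: OpsinSet,
    pocket,
    reference_key=None,
) -> list:
    """Evaluate every pocket site against the duplicate-divergence filters.

    ``pocket`` is a list of :class:`PocketSite` or of 1-based positions in
    the reference sequence (``reference_key`` defaults to the first key of
    the first species).  A site is a candidate when it is variant between
    the duplicates in *every* species, invariant across species within each
    duplicate, and its substitution is structurally significant.  Sites
    failing only the significance test are retained with
    ``candidate=False``.
    """
    if opsins.alignment is None:
        raise ValueError("OpsinSet must be aligned for screening")
    species = opsins.species
    copies = opsins.copies
    if len(copies) != 2:
        raise ValueError(f"screen needs exactly two duplicate copies, got {copies}")
    if len(species) < 2:
        raise ValueError("screen needs at least two species")
    for sp in species:
        for cp in copies:
            if (sp, cp) not in opsins.sequences:
                raise ValueError(f"missing duplicate {cp!r} for species {sp!r}")
    if reference_key is None:
        reference_key = (species[0], copies[0])

    records = []
    for site in pocket:
        if not isinstance(site, PocketSite):
            site = PocketSite(position_ref=int(site))
        residues = {}
        for key in opsins.sequences:
            pos = map_site(opsins.alignment, reference_key, key, site.position_ref)
            residues[key] = None if pos is None else opsins.sequences[key][pos - 1]
        variant = {
            sp: residues[(sp, copies[0])] != residues[(sp, copies[1])] for sp in species
        }
        invariant = {
            cp: len({residues[(sp, cp)] for sp in species}) == 1 for cp in copies
        }
        ref_sp = reference_key[0]
        r1, r2 = residues[(ref_sp, copies[0])], residues[(ref_sp, copies[1])]
        if r1 is None or r2 is None:
            cls = SubstitutionClass((r1 or "-", r2 or "-"), False, False, False, False)
        else:
            cls = classify_substitution(r1, r2)
        candidate = (
            all(variant.values()) and all(invariant.values()) and cls.significant
        )
        records.append(
            SiteRecord(
                site=site,
                residues_by_key=residues,
                variant_between_duplicates=variant,
                invariant_across_species=invariant,
                classification=cls,
                candidate=candidate,
            )
        )
    return sorted(records, key=lambda r: r.site.position_ref)
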