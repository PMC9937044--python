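"""Pairwise identity, coordinate mapping, substitution classes, pocket, screen."""

import itertools

import numpy as np
import pytest

from opsintune.screen import (
    AA_VOLUME,
    BOVINE_RHODOPSIN,
    OpsinSet,
    PocketSite,
    align_pair,
    classify_substitution,
    map_site,
    pairwise_identity,
    pocket_sites_from_structure,
    screen_candidates,
)
from conftest import AA, toy_pdb


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 100

    def test_four_of_five(self):
        assert pairwise_identity("ACDEF", "ACDFF") == 80

    def test_symmetric(self):
        a, b = "MKQLVITWYAAC", "MKELVITWYGAC"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_planted_divergence_count(self):
        """Substituting exactly k of n positions gives identity (n-k)/n."""
        rng = np.random.default_rng(17)
        aas = np.array(list(AA))
        base = rng.choice(aas, size=200)
        mutant = base.copy()
        pos = rng.choice(200, size=20, replace=False)
        for p in pos:
            mutant[p] = rng.choice(aas[aas != base[p]])
        assert pairwise_identity("".join(base), "".join(mutant)) == 90

    def test_non_amino_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino"):
            pairwise_identity("ACDEF", "AC1EF")

    def test_x_is_tolerated(self):
        assert pairwise_identity("ACXEF", "ACXEF") == 100


class TestMapSite:
    def test_self_alignment_identity(self):
        aln = {"a": "MKQLV", "b": "MKQLV"}
        for p in range(1, 6):
            assert map_site(aln, "a", "b", p) == p

    def test_toy_alignment_counted_by_hand(self):
        aln = {"A": "MK-LV", "B": "MKQLV"}
        assert map_site(aln, "A", "B", 3) == 4  # L in A sits in column 4
        assert map_site(aln, "B", "A", 3) is None  # Q aligns to a gap in A

    def test_round_trip_where_no_gap(self):
        aln = {"A": "MK-LVW", "B": "MKQLV-"}
        for p in range(1, 6):
            q = map_site(aln, "A", "B", p)
            if q is not None:
                assert map_site(aln, "B", "A", q) == p

    def test_missing_key_rejected(self):
        with pytest.raises(KeyError):
            map_site({"A": "MKQ"}, "A", "Z", 1)

    def test_position_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            map_site({"A": "MK-", "B": "MKQ"}, "A", "B", 3)

    def test_bovine_reference_round_trip(self):
        """Aligning bovine rhodopsin against a gapped variant of itself maps
        positions consistently in both directions."""
        variant = BOVINE_RHODOPSIN[:100] + BOVINE_RHODOPSIN[110:]  # 10-aa deletion
        a, b = align_pair(BOVINE_RHODOPSIN, variant)
        aln = {"bov": a, "var": b}
        assert map_site(aln, "bov", "var", 50) == 50
        assert map_site(aln, "bov", "var", 200) == 190


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "pair,expected_flags,significant",
        [
            (("A", "Q"), {"polarity_change", "size_change"}, True),
            (("Y", "F"), {"polarity_change", "hydroxyl_change"}, True),
            (("S", "T"), set(), False),
            (("C", "V"), {"disulfide_change"}, True),
            (("I", "L"), set(), False),
            (("S", "A"), {"polarity_change", "hydroxyl_change"}, True),
            (("T", "C"), {"polarity_change", "hydroxyl_change", "disulfide_change"}, True),
        ],
    )
    def test_published_site_pairs(self, pair, expected_flags, significant):
        c = classify_substitution(*pair)
        flags = {
            name
            for name in ("polarity_change", "hydroxyl_change", "size_change",
                         "disulfide_change")
            if getattr(c, name)
        }
        assert flags == expected_flags
        assert c.significant == significant

    def test_symmetric_for_all_pairs(self):
        for a, b in itertools.product(AA, repeat=2):
            ca, cb = classify_substitution(a, b), classify_substitution(b, a)
            assert (ca.polarity_change, ca.hydroxyl_change, ca.size_change,
                    ca.disulfide_change) == (
                cb.polarity_change, cb.hydroxyl_change, cb.size_change,
                cb.disulfide_change)

    def test_identity_pairs_never_significant(self):
        for a in AA:
            assert not classify_substitution(a, a).significant

    def test_label_composition(self):
        assert classify_substitution("A", "Q").label == "Change in polarity and size"
        assert classify_substitution("Y", "F").label == "Change in polarity and hydroxyl group"
        assert classify_substitution("I", "L").label == "Most likely insignificant"
        assert classify_substitution("C", "V").label == "Change in disulfide bonding"

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            classify_substitution("A", "X")

    def test_volume_table_complete(self):
        assert set(AA_VOLUME) == set(AA)


class TestPocketExtraction:
    def test_distance_threshold_by_construction(self, tmp_path):
        pdb = toy_pdb([(3.0, 0, 0), (0, 4.9, 0), (0, 0, 5.1)], [(0.0, 0.0, 0.0)])
        path = tmp_path / "toy.pdb"
        path.write_text(pdb)
        sites = pocket_sites_from_structure(path, cutoff=5.0)
        assert [s.position_ref for s in sites] == [1, 2]

    def test_zero_cutoff_empty(self, tmp_path):
        pdb = toy_pdb([(1.0, 0, 0)], [(0.0, 0.0, 0.0)])
        path = tmp_path / "toy.pdb"
        path.write_text(pdb)
        assert pocket_sites_from_structure(path, cutoff=0.0) == []

    def test_no_ligand_rejected(self, tmp_path):
        pdb = toy_pdb([(1.0, 0, 0)], [])
        path = tmp_path / "toy.pdb"
        path.write_text(pdb)
        with pytest.raises(ValueError, match="ligand"):
            pocket_sites_from_structure(path)

    def test_matches_brute_force_distance_oracle(self, tmp_path):
        rng = np.random.default_rng(99)
        res = rng.uniform(-15, 15, size=(50, 3))
        lig = rng.uniform(-3, 3, size=(4, 3))
        path = tmp_path / "rand.pdb"
        path.write_text(toy_pdb([tuple(r) for r in res], [tuple(l) for l in lig]))
        sites = pocket_sites_from_structure(path, cutoff=5.0)
        # independent brute-force oracle over all residue/ligand atom pairs
        expected = [
            i + 1
            for i in range(50)
            if np.sqrt(((res[i] - lig) ** 2).sum(axis=1)).min() <= 5.0
        ]
        assert [s.position_ref for s in sites] == expected


class TestScreen:
    def _family(self, planted, n_species=2, seed=5, length=120):
        from opsintune.simulate import simulate_opsin_family

        return simulate_opsin_family(
            base_length=length,
            n_species=n_species,
            planted_sites=planted,
            pocket_decoys=4,
            seed=seed,
        )

    def test_planted_significant_site_is_the_only_candidate(self):
        opsins, pocket = self._family([(50, "A", "Q")])
        recs = screen_candidates(opsins, pocket)
        cands = [r.site.position_ref for r in recs if r.candidate]
        assert cands == [50]

    def test_identical_sequences_yield_no_variants(self):
        opsins, pocket = self._family([])
        recs = screen_candidates(opsins, pocket)
        assert all(not any(r.variant_between_duplicates.values()) for r in recs)
        assert not any(r.candidate for r in recs)

    def test_insignificant_variant_retained_but_not_candidate(self):
        opsins, pocket = self._family([(50, "S", "T")])
        recs = {r.site.position_ref: r for r in screen_candidates(opsins, pocket)}
        r = recs[50]
        assert all(r.variant_between_duplicates.values())
        assert not r.candidate
        assert r.classification.label == "Most likely insignificant"

    def test_output_is_subset_of_pocket_and_sorted(self):
        opsins, pocket = self._family([(50, "A", "Q"), (20, "Y", "F")])
        recs = screen_candidates(opsins, pocket)
        positions = [r.site.position_ref for r in recs]
        assert positions == sorted(positions)
        assert set(positions) == set(pocket)

    def test_removing_a_species_cannot_shrink_candidate_set(self):
        opsins, pocket = self._family([(50, "A", "Q"), (70, "C", "V")], n_species=3)
        recs_all = screen_candidates(opsins, pocket)
        cands_all = {r.site.position_ref for r in recs_all if r.candidate}
        keep = [sp for sp in opsins.species][:2]
        sub = OpsinSet(
            sequences={k: v for k, v in opsins.sequences.items() if k[0] in keep},
            alignment={k: v for k, v in opsins.alignment.items() if k[0] in keep},
        )
        recs_sub = screen_candidates(sub, pocket)
        cands_sub = {r.site.position_ref for r in recs_sub if r.candidate}
        assert cands_all <= cands_sub

    def test_missing_duplicate_rejected(self):
        opsins, pocket = self._family([(50, "A", "Q")])
        seqs = dict(opsins.sequences)
        aln = dict(opsins.alignment)
        key = next(k for k in seqs if k[1] == "copy2")
        del seqs[key], aln[key]
        broken = OpsinSet(sequences=seqs, alignment=aln)
        with pytest.raises(ValueError, match="missing|copies"):
            screen_candidates(broken, pocket)

    def test_table1_style_family_reproduces_bold_candidates(self, table1_family):
        uv, uv_sites, lw, lw_sites = table1_family
        uv_recs = screen_candidates(uv, uv_sites, reference_key=("rajah", "UV2"))
        lw_recs = screen_candidates(lw, lw_sites, reference_key=("rajah", "LW2"))
        assert [r.site.position_ref for r in uv_recs if r.candidate] == [198, 285]
        assert [r.site.position_ref for r in lw_recs if r.candidate] == [140, 227]
        by_pos = {r.site.position_ref: r for r in uv_recs}
        assert not by_pos[130].candidate and not by_pos[217].candidate
        # site 316: filtered by cross-species invariance, not significance
        assert by_pos[316].classification.significant
        assert not by_pos[316].candidate
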