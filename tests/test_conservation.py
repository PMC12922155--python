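from __future__ import annotations

import itertools

import numpy as np
import pytest

from abaphos.conservation import (
    CATEGORY_CONSERVED_RESIDUE,
    CATEGORY_CONSERVED_RESPONSIVE,
    CATEGORY_NOT_CONSERVED,
    CATEGORY_UNALIGNABLE,
    classify_site,
    conservation_matrix,
    map_site,
    needleman_wunsch_align,
    responsive_group_sets,
    venn_counts,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestGroupSets:
    def test_set_semantics(self):
        membership = {"ath": {"A1": "G1", "A2": "G1", "A3": "G2"}}
        sets, missing = responsive_group_sets(membership, {"ath": ["A1", "A2", "A4"]})
        assert sets["ath"] == {"G1"}
        assert missing["ath"] == 1  # A4 has no group


class TestConservationMatrix:
    def _fixture(self):
        # ath responsive A1..A4; A1,A2,A3 in groups; A4 ungrouped.
        # G1 has osa member that is responsive; G2 has osa member, silent;
        # G3 has no osa member.
        membership = {
            "ath": {"A1": "G1", "A2": "G2", "A3": "G3"},
            "osa": {"O1": "G1", "O2": "G2"},
        }
        presence = {"ath": {"G1", "G2", "G3"}, "osa": {"G1", "G2"}}
        responsive = {"ath": ["A1", "A2", "A3", "A4"], "osa": ["O1"]}
        sets, _ = responsive_group_sets(membership, responsive)
        return membership, presence, responsive, sets

    def test_counts_and_ordering_invariant(self):
        membership, presence, responsive, sets = self._fixture()
        m = conservation_matrix("ath", responsive, membership, presence, sets)
        assert m.n_responsive == 4
        assert m.per_target["osa"] == (2, 1)  # A1,A2 have osa orthologs; only G1 responsive
        assert m.rates["osa"] == (50.0, 25.0)
        with_orth, orth_resp = m.per_target["osa"]
        assert orth_resp <= with_orth <= m.n_responsive

    def test_rates_use_printed_denominator_convention(self):
        # rates are percentages of the reference responsive-protein count
        membership = {"ath": {f"A{i}": f"G{i}" for i in range(1137)},
                      "osa": {f"O{i}": f"G{i}" for i in range(1103)}}
        presence = {"ath": set(membership["ath"].values()), "osa": set(membership["osa"].values())}
        responsive = {"ath": [f"A{i}" for i in range(1137)], "osa": [f"O{i}" for i in range(595)]}
        sets, _ = responsive_group_sets(membership, responsive)
        m = conservation_matrix("ath", responsive, membership, presence, sets)
        assert m.per_target["osa"] == (1103, 595)
        assert m.rates["osa"] == (97.0, 52.3)

    def test_zero_counts(self):
        membership = {"ath": {"A1": "G1"}, "osa": {}}
        presence = {"ath": {"G1"}, "osa": set()}
        responsive = {"ath": ["A1"], "osa": []}
        sets, _ = responsive_group_sets(membership, responsive)
        m = conservation_matrix("ath", responsive, membership, presence, sets)
        assert m.per_target["osa"] == (0, 0) and m.rates["osa"] == (0.0, 0.0)


class TestVenn:
    def test_triple_region(self):
        venn = venn_counts({"a": {1, 2}, "b": {2, 3}, "c": {2}})
        assert venn.regions["A"] == frozenset({2})
        assert venn.counts() == {"A": 1, "B": 0, "C": 0, "D": 0, "E": 1, "F": 1, "G": 0}

    def test_disjoint_sets(self):
        venn = venn_counts({"a": {1}, "b": {2}, "c": {3}})
        assert all(venn.counts()[t] == 0 for t in ("A", "B", "C", "D"))

    def test_pairwise_overlap_percentage(self):
        ref = {f"g{i}" for i in range(624)}
        other = {f"g{i}" for i in range(480)} | {f"x{i}" for i in range(277)}
        venn = venn_counts({"osa": ref, "gma": other, "ath": set()})
        assert venn.pairwise_overlap_pct("osa", "gma") == 76.9

    def test_regions_partition_union_and_totals(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            sets = {
                sp: set(rng.integers(0, 40, size=rng.integers(0, 30)).tolist())
                for sp in ("x", "y", "z")
            }
            if not all(sets.values()):
                continue
            venn = venn_counts(sets)
            union = set().union(*sets.values())
            assert sum(venn.counts().values()) == len(union)
            for sp in sets:
                assert venn.species_total(sp) == len(sets[sp])
            # brute-force enumeration oracle
            for element in union:
                pattern = tuple(element in sets[sp] for sp in ("x", "y", "z"))
                tag = {
                    (True, True, True): "A",
                    (True, True, False): "B",
                    (True, False, True): "C",
                    (False, True, True): "D",
                    (True, False, False): "E",
                    (False, True, False): "F",
                    (False, False, True): "G",
                }[pattern]
                assert element in venn.regions[tag]

    def test_permutation_invariance_of_region_contents(self):
        sets = {"a": {1, 2, 3}, "b": {2, 3, 4}, "c": {3, 4, 5}}
        base = venn_counts(sets)
        for order in itertools.permutations(sets):
            permuted = venn_counts({sp: sets[sp] for sp in order})
            assert permuted.regions["A"] == base.regions["A"]
            for sp in sets:
                assert permuted.species_total(sp) == base.species_total(sp)

    def test_requires_three_species(self):
        with pytest.raises(ValueError):
            venn_counts({"a": {1}, "b": {2}})


class TestAlignment:
    def test_identical_sequences_align_gapless(self):
        aln = needleman_wunsch_align("MKSAPRDE", "MKSAPRDE")
        assert aln.aligned_a == aln.aligned_b == "MKSAPRDE"

    def test_single_deletion(self):
        aln = needleman_wunsch_align("ACD", "AD")
        assert aln.aligned_a == "ACD" and aln.aligned_b == "A-D"

    def test_score_matches_brute_force_dp(self):
        import random

        from _oracles import gotoh_score

        rng = random.Random(11)
        for _ in range(40):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            assert needleman_wunsch_align(a, b).score == pytest.approx(gotoh_score(a, b, mode="global"))


class TestMapSite:
    def test_identity_alignment_maps_identically(self):
        aln = needleman_wunsch_align("MKSAPRDE", "MKSAPRDE")
        assert map_site(aln, 3) == (3, "S")

    def test_insertion_in_partner_shifts_position(self):
        # partner has 3 extra residues before the site
        aln = needleman_wunsch_align("MKKKSAPRDEF", "MWWWKKKSAPRDEF")
        assert map_site(aln, 5) == (8, "S")

    def test_site_on_gap_column(self):
        aln = needleman_wunsch_align("ACD", "AD")
        assert map_site(aln, 2) == (None, None)

    def test_out_of_range_is_error(self):
        aln = needleman_wunsch_align("ACD", "AD")
        with pytest.raises(ValueError):
            map_site(aln, 4)

    def test_monotone_and_round_trip(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=60))
            b = a[:20] + a[25:40] + "WWW" + a[40:]  # deletion + insertion
            aln = needleman_wunsch_align(a, b)
            back = needleman_wunsch_align(b, a)
            mapped = [(p, map_site(aln, p)[0]) for p in range(1, 61)]
            non_gap = [(p, q) for p, q in mapped if q is not None]
            for (p1, q1), (p2, q2) in zip(non_gap, non_gap[1:]):
                assert p1 < p2 and q1 < q2
            for p, q in non_gap:
                assert map_site(back, q)[0] == p


class TestClassifySite:
    def _aln(self, a, b):
        return needleman_wunsch_align(a, b)

    def test_conserved_responsive(self):
        aln = self._aln("MKKSAPRDEKLM", "MKKSAPRDEKLM")
        assert classify_site(aln, 4, {4}, bit_floor=0) == CATEGORY_CONSERVED_RESPONSIVE

    def test_conserved_residue_only(self):
        aln = self._aln("MKKSAPRDEKLM", "MKKSAPRDEKLM")
        assert classify_site(aln, 4, set(), bit_floor=0) == CATEGORY_CONSERVED_RESIDUE

    def test_position_not_conserved_by_residue(self):
        aln = self._aln("MKKSAPRDEKLM", "MKKAAPRDEKLM")
        assert classify_site(aln, 4, {4}, bit_floor=0) == CATEGORY_NOT_CONSERVED

    def test_gap_is_position_not_conserved(self):
        aln = self._aln("ACSDEFGHIKLM", "ACDEFGHIKLM")
        # find which column S occupies; S deleted in partner
        assert classify_site(aln, 3, set(), bit_floor=0) in (
            CATEGORY_NOT_CONSERVED,
            CATEGORY_CONSERVED_RESIDUE,
        )

    def test_unalignable_below_bit_floor(self):
        aln = self._aln("MKKSAPRDEKLM", "MKKSAPRDEKLM")
        assert classify_site(aln, 4, {4}, bit_floor=1e6) == CATEGORY_UNALIGNABLE
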