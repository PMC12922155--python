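from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from abaphos.quant_io import REPLICATES, TIMEPOINTS, PhosphoPeptide
from abaphos.responsiveness import (
    StatConfig,
    abundance_matrix,
    call_all,
    call_responsive,
    collapse_to_proteins,
    fold_change,
    pca_qc,
    responsive_sites,
    student_t_test,
)

from _oracles import pooled_t_pvalue


def block(baseline, t15=None, t30=None, t90=None):
    """Abundance dict from per-timepoint replicate triples."""
    groups = {0: baseline, 15: t15 or baseline, 30: t30 or baseline, 90: t90 or baseline}
    return {
        (t, r): (groups[t][r - 1] if groups[t] is not None and groups[t][r - 1] is not None else None)
        for t in TIMEPOINTS
        for r in REPLICATES
    }


def peptide(abundances, peptide_id="p", accession="P1", sites=((3, "S"),)):
    return PhosphoPeptide(
        peptide_id=peptide_id,
        bare_sequence="MKSAPR",
        protein_accession=accession,
        species="ath",
        sites=list(sites),
        abundances=abundances,
    )


class TestFoldChange:
    def test_exact_ratio(self):
        assert fold_change([4, 4, 4], [2, 2, 2]) == pytest.approx(2.0)

    def test_identity(self):
        assert fold_change([3, 5, 7], [3, 5, 7]) == pytest.approx(1.0)

    def test_insufficient_replicates_not_testable(self):
        assert fold_change([4.0], [2, 2, 2]) is None
        assert fold_change([4, 4], [2.0]) is None

    def test_zero_baseline_not_testable(self):
        assert fold_change([4, 4, 4], [0, 0, 0]) is None

    def test_planted_threefold_recovered_in_noise(self):
        # 3.0-fold responder under log-normal noise (sigma=0.2 on log2), n=3:
        # the estimate should land within +/-35% of 3.0 in >=95% of runs
        rng = np.random.default_rng(2024)
        ok = 0
        n_sim = 1000
        for _ in range(n_sim):
            baseline = 2.0 ** (10 + rng.normal(0, 0.2, size=3))
            treated = 2.0 ** (10 + math.log2(3.0) + rng.normal(0, 0.2, size=3))
            fc = fold_change(list(treated), list(baseline))
            if abs(fc - 3.0) <= 0.35 * 3.0:
                ok += 1
        assert ok / n_sim >= 0.95


class TestStudentTTest:
    def test_matches_textbook_oracle(self):
        cases = [
            ([6.0, 6.2, 6.1], [5.0, 5.1, 4.9]),
            ([1.0, 2.0, 3.0, 4.0], [2.0, 2.5, 3.5]),
            ([10.0, 10.1], [10.4, 10.2, 10.3]),
        ]
        for x, y in cases:
            assert student_t_test(x, y) == pytest.approx(pooled_t_pvalue(x, y), abs=1e-10)

    def test_identical_groups_give_p_one(self):
        assert student_t_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_zero_variance_different_means_give_p_zero(self):
        assert student_t_test([5.0, 5.0], [6.0, 6.0]) == 0.0

    def test_symmetry_under_label_swap(self):
        x, y = [6.0, 6.2, 6.1], [5.0, 5.1, 4.9]
        assert student_t_test(x, y) == pytest.approx(student_t_test(y, x))

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [2.0, 3.0])


class TestCallResponsive:
    def test_responsive_at_one_timepoint_records_first(self):
        pep = peptide(
            block([100, 101, 99], t15=[105, 100, 102], t30=[410, 395, 405], t90=[150, 148, 152])
        )
        call = call_responsive(pep)
        assert call.responsive
        assert call.first_responsive_timepoint == 30
        assert call.fold_change[30] == pytest.approx(4.0, rel=0.05)

    def test_fc_gate_alone_is_not_enough(self):
        # huge fold change but wildly variable replicates -> p too large
        pep = peptide(block([100, 101, 99], t30=[150, 4000, 120]))
        call = call_responsive(pep)
        assert call.p_value[30] > 0.05 and not call.responsive

    def test_exact_twofold_fails_strict_gate(self):
        pep = peptide(block([100.0, 100.0, 100.0], t15=[200.0, 200.0, 200.0]))
        call = call_responsive(pep)
        assert call.fold_change[15] == pytest.approx(2.0)
        assert call.p_value[15] == 0.0  # zero-variance convention
        assert not call.responsive  # FC must be strictly > 2

    def test_all_missing_flags_insufficient_data(self):
        pep = peptide({(t, r): None for t in TIMEPOINTS for r in REPLICATES})
        call = call_responsive(pep)
        assert not call.responsive and call.insufficient_data

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = {
                (t, r): float(2.0 ** (12 + rng.normal(0, 0.5)))
                for t in TIMEPOINTS
                for r in REPLICATES
            }
            pep1 = peptide(values)
            pep2 = peptide({k: v * 1734.5 for k, v in values.items()})
            c1, c2 = call_responsive(pep1), call_responsive(pep2)
            assert c1.responsive == c2.responsive
            for t in (15, 30, 90):
                assert c1.fold_change[t] == pytest.approx(c2.fold_change[t])
                assert c1.p_value[t] == pytest.approx(c2.p_value[t])


class TestProteinCollapse:
    def test_two_peptides_one_protein(self):
        peps = [
            peptide(block([100, 100, 101], t15=[500, 505, 498]), "p1", "P1"),
            peptide(block([100, 100, 101], t15=[500, 505, 498]), "p2", "P1"),
            peptide(block([100, 100, 101]), "p3", "P2"),
        ]
        calls = call_all(peps)
        assert collapse_to_proteins(calls) == ["P1"]

    def test_no_responsive_peptides(self):
        calls = call_all([peptide(block([100, 100, 101]), "p1", "P1")])
        assert collapse_to_proteins(calls) == []

    def test_size_bounded_by_responsive_peptides(self, small_bundle):
        from abaphos.quant_io import read_phosphopeptide_table

        peptides = read_phosphopeptide_table(small_bundle / "ath_phospho.tsv", "ath")
        calls = call_all(peptides)
        n_resp = sum(c.responsive for c in calls)
        assert len(collapse_to_proteins(calls)) <= n_resp

    def test_responsive_sites_union(self):
        peps = [
            peptide(block([100, 100, 101], t15=[500, 505, 498]), "p1", "P1", sites=[(3, "S")]),
            peptide(block([100, 100, 101], t15=[500, 505, 498]), "p2", "P1", sites=[(3, "S"), (5, "S")]),
        ]
        calls = call_all(peps)
        assert responsive_sites(calls, peps) == {"P1": {3, 5}}


class TestPcaQc:
    def test_two_groups_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1, size=50)
        cols = {}
        for r in range(3):
            cols[f"t0_r{r+1}"] = base + rng.normal(0, 0.05, 50)
            cols[f"t90_r{r+1}"] = base + 2.0 + rng.normal(0, 0.05, 50)
        scores = pca_qc(pd.DataFrame(cols))
        pc1_0 = scores.loc[[c for c in scores.index if c.startswith("t0")], "PC1"]
        pc1_90 = scores.loc[[c for c in scores.index if c.startswith("t90")], "PC1"]
        assert pc1_0.max() < pc1_90.min() or pc1_90.max() < pc1_0.min()

    def test_identical_columns_give_zero_scores(self):
        col = np.arange(10.0)
        scores = pca_qc(pd.DataFrame({f"s{i}": col for i in range(4)}))
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_too_few_complete_rows_skips(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, np.nan]})
        assert pca_qc(df) is None

    def test_planted_timepoint_shift_separates_samples(self):
        # 30% of peptides shifted between 0 and 90 min: silhouette of the
        # timepoint grouping on PC1-PC2 should exceed 0.5
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        n_pep = 300
        base = rng.normal(12, 2, size=n_pep)
        shifted = rng.random(n_pep) < 0.3
        cols = {}
        for r in range(3):
            cols[f"t0_r{r+1}"] = base + rng.normal(0, 0.15, n_pep)
            cols[f"t90_r{r+1}"] = base + shifted * 1.5 + rng.normal(0, 0.15, n_pep)
        scores = pca_qc(pd.DataFrame(cols))
        labels = [0 if s.startswith("t0") else 1 for s in scores.index]
        assert silhouette_score(scores.to_numpy(), labels) > 0.5

    def test_matrix_round_trip_from_peptides(self):
        pep = peptide(block([100, 100, 100]))
        mat = abundance_matrix([pep])
        assert mat.shape == (1, 12)
        assert mat.loc["p", "t0_r1"] == pytest.approx(math.log2(100))


def test_null_rejection_rate_within_binomial_bounds():
    """No planted effect, n=3 vs 3, 1000 peptides: the t-test rejects at
    alpha=0.05 at a rate inside the binomial 99% interval, and the full
    responsive rule (FC and p over three timepoints) fires less often than
    the p-gate alone."""
    rng = np.random.default_rng(1234)
    n_pep = 1000
    p_gate = 0
    responsive = 0
    config = StatConfig()
    for i in range(n_pep):
        base = 14 + rng.normal(0, 1)
        values = {
            (t, r): float(2.0 ** (base + rng.normal(0, 0.3))) for t in TIMEPOINTS for r in REPLICATES
        }
        call = call_responsive(peptide(values, f"p{i}"), config)
        if call.p_value[15] is not None and call.p_value[15] < 0.05:
            p_gate += 1
        responsive += call.responsive
    se = math.sqrt(0.05 * 0.95 / n_pep)
    assert abs(p_gate / n_pep - 0.05) <= 2.576 * se
    assert responsive <= p_gate
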