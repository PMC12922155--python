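"""Calling ABA-responsive phosphopeptides and proteins.

A phosphopeptide is called responsive when its abundance is significantly
increased relative to the 0 min baseline — fold change strictly above the
threshold (default 2) AND Student's t-test p strictly below alpha (default
0.05) — at at least one post-treatment timepoint (15, 30, or 90 min).

Fold change is the ratio of linear-scale replicate means; the t-test is the
classical pooled-variance two-sample test on log2 abundances (Welch
available behind a flag). No multiple-testing correction is applied by
default (raw p < alpha), matching common label-free phosphoproteomics
practice; Benjamini-Hochberg is available as an option.

A timepoint is testable only when both it and the baseline have at least
``min_replicates`` non-missing values; not-testable timepoints can never
make a peptide responsive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quant_io import PhosphoPeptide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatConfig:
    fc_threshold: float = 2.0
    alpha: float = 0.05
    timepoints_tested: tuple[int, ...] = (15, 30, 90)
    min_replicates_per_condition: int = 2
    direction: str = "increase"
    welch: bool = False
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ResponsivenessCall:
    peptide_id: str
    protein_accession: str
    fold_change: dict[int, float | None] = field(default_factory=dict)
    p_value: dict[int, float | None] = field(default_factory=dict)
    responsive: bool = False
    first_responsive_timepoint: int | None = None
    insufficient_data: bool = False


def fold_change(
    treated: list[float], baseline: list[float], min_replicates: int = 2
) -> float | None:
    """mean(treated)/mean(baseline) on the linear scale; None if not testable."""
    if len(treated) < min_replicates or len(baseline) < min_replicates:
        return None
    mb = float(np.mean(baseline))
    if mb == 0.0:
        return None
    return float(np.mean(treated)) / mb


def student_t_test(treated_log2: list[float], baseline_log2: list[float], welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value on log2 abundances.

    Zero-variance convention: identical group means give p = 1.0, different
    means with zero pooled variance give p = 0.0.
    """
    x = np.asarray(treated_log2, dtype=float)
    y = np.asarray(baseline_log2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.pvalue)


def call_responsive(peptide: PhosphoPeptide, config: StatConfig = StatConfig()) -> ResponsivenessCall:
    call = ResponsivenessCall(peptide_id=peptide.peptide_id, protein_accession=peptide.protein_accession)
    baseline = peptide.condition(0)
    any_testable = False
    for t in config.timepoints_tested:
        treated = peptide.condition(t)
        fc = fold_change(treated, baseline, config.min_replicates_per_condition)
        if fc is None or min(treated) <= 0 or min(baseline) <= 0:
            call.fold_change[t] = fc
            call.p_value[t] = None
            continue
        any_testable = True
        p = student_t_test(
            [math.log2(v) for v in treated], [math.log2(v) for v in baseline], welch=config.welch
        )
        call.fold_change[t] = fc
        call.p_value[t] = p
    if config.bh_correct:
        _apply_bh_within_call(call, config)
    for t in config.timepoints_tested:
        fc, p = call.fold_change.get(t), call.p_value.get(t)
        if fc is not None and p is not None and fc > config.fc_threshold and p < config.alpha:
            call.responsive = True
            call.first_responsive_timepoint = t
            break
    call.insufficient_data = not any_testable
    return call


def _apply_bh_within_call(call: ResponsivenessCall, config: StatConfig) -> None:
    # BH is applied per peptide across its tested timepoints; off by default.
    items = [(t, p) for t, p in call.p_value.items() if p is not None]
    if not items:
        return
    m = len(items)
    order = sorted(items, key=lambda tp: tp[1])
    adjusted: dict[int, float] = {}
    prev = 1.0
    for rank, (t, p) in reversed(list(enumerate(order, start=1))):
        prev = min(prev, p * m / rank)
        adjusted[t] = prev
    for t in adjusted:
        call.p_value[t] = adjusted[t]


def call_all(peptides: list[PhosphoPeptide], config: StatConfig = StatConfig()) -> list[ResponsivenessCall]:
    return [call_responsive(p, config) for p in peptides]


def collapse_to_proteins(calls: list[ResponsivenessCall]) -> list[str]:
    """Proteins with at least one responsive phosphopeptide, sorted and deduplicated."""
    return sorted({c.protein_accession for c in calls if c.responsive})


def responsive_sites(
    calls: list[ResponsivenessCall], peptides: list[PhosphoPeptide]
) -> dict[str, set[int]]:
    """Per-protein set of phosphosite positions carried by responsive peptides."""
    by_id = {p.peptide_id: p for p in peptides}
    out: dict[str, set[int]] = {}
    for call in calls:
        if not call.responsive:
            continue
        pep = by_id[call.peptide_id]
        out.setdefault(pep.protein_accession, set()).update(pos for pos, _res in pep.sites)
    return out


def calls_to_frame(calls: list[ResponsivenessCall], config: StatConfig = StatConfig()) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "peptide_id": c.peptide_id,
            "protein_accession": c.protein_accession,
        }
        for t in config.timepoints_tested:
            row[f"fc_{t}"] = c.fold_change.get(t)
            row[f"p_{t}"] = c.p_value.get(t)
        row["responsive"] = c.responsive
        row["first_responsive_timepoint"] = c.first_responsive_timepoint
        rows.append(row)
    return pd.DataFrame(rows)


def abundance_matrix(peptides: list[PhosphoPeptide]) -> pd.DataFrame:
    """Peptides x samples matrix of log2 abundances (NaN for missing)."""
    data = {}
    for pep in peptides:
        data[pep.peptide_id] = {
            f"t{t}_r{r}": (np.log2(v) if (v := pep.abundances.get((t, r))) else np.nan)
            for (t, r) in pep.abundances
        }
    return pd.DataFrame.from_dict(data, orient="index")


def pca_qc(log2_matrix: pd.DataFrame) -> pd.DataFrame | None:
    """Sample scores on the first two principal components of the quant matrix.

    Rows (peptides) with any missing value are dropped for the PCA only;
    fewer than 3 complete rows skips QC with a warning. Components carry a
    deterministic sign convention: the largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    complete = log2_matrix.dropna(axis=0, how="any")
    if complete.shape[0] < 3:
        logger.warning("PCA QC skipped: only %d complete rows", complete.shape[0])
        return None
    X = complete.to_numpy().T  # samples x peptides
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(scores.shape[1]):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=complete.columns, columns=["PC1", "PC2"])
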