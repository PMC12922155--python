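"""Independent brute-force oracles used only by the tests.

These are deliberately naive re-derivations (plain-Python DP, direct
summation, closed forms) kept separate from the package implementation.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


def _scorer(matrix_name: str = "BLOSUM62"):
    mat = substitution_matrices.load(matrix_name)

    def score(x: str, y: str) -> float:
        if x == "X" or y == "X":
            return 0.0
        return float(mat[x, y])

    return score


def gotoh_score(
    seq_a: str,
    seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    mode: str = "local",
    matrix_name: str = "BLOSUM62",
) -> float:
    """Three-state affine-gap DP (first gap residue costs open+extend)."""
    s = _scorer(matrix_name)
    local = mode == "local"
    go = gap_open + gap_extend
    ge = gap_extend
    n, m = len(seq_a), len(seq_b)
    H = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq_a (consume b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq_b (consume a)
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = max(H[0][j - 1] - go, E[0][j - 1] - ge)
        H[0][j] = 0.0 if local else E[0][j]
    for i in range(1, n + 1):
        F[i][0] = max(H[i - 1][0] - go, F[i - 1][0] - ge)
        H[i][0] = 0.0 if local else F[i][0]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            diag = H[i - 1][j - 1] + s(seq_a[i - 1], seq_b[j - 1])
            h = max(diag, E[i][j], F[i][j])
            if local:
                h = max(h, 0.0)
                best = max(best, h)
            H[i][j] = h
    return best if local else H[n][m]


def binomial_tail_direct(k: int, n: int, p0: float) -> float:
    """P(X >= k) by direct summation of the smaller tail."""
    if k == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0

    def pmf(i: int) -> float:
        return math.comb(n, i) * (p0**i) * ((1 - p0) ** (n - i))

    if k <= n * p0:
        return max(0.0, min(1.0, 1.0 - sum(pmf(i) for i in range(k))))
    return max(0.0, min(1.0, sum(pmf(i) for i in range(k, n + 1))))


def pooled_t_pvalue(x: list[float], y: list[float]) -> float:
    """Textbook two-sided pooled-variance two-sample t-test."""
    from scipy.stats import t as tdist

    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    ss1 = sum((v - m1) ** 2 for v in x)
    ss2 = sum((v - m2) ** 2 for v in y)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    tstat = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * tdist.sf(abs(tstat), df)
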