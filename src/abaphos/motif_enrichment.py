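"""Iterative phosphorylation-motif enrichment (motif-x style).

Foreground: 13-residue windows (offsets -6..+6) centered on responsive
phosphosites. Background: windows around every S/T/Y in the full proteome
of the species ("all registered genes"). Per center class (S and T pooled
into S/T; Y separate) the procedure repeatedly

1. scores every unfixed (offset, residue) pair with a binomial upper-tail
   p-value of its foreground count against the current background frequency,
2. fixes the most significant pair if it passes the thresholds
   (count strictly > ``min_occurrence``, p strictly < ``p_threshold``),
3. reduces foreground and background to windows matching the pair,

until no pair qualifies; the accumulated fixed pairs form one motif, its
matching foreground windows are removed from the pool, the background is
restored, and the search restarts. Background frequencies are recomputed
from the reduced background at every fixing step, as in canonical motif-x.

Windows overhanging protein termini are padded with '_'; the pad never
matches a motif and is excluded from frequency denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class Window:
    """A fixed-width sequence window centered on a phosphosite candidate."""

    residues: str
    origin: tuple[str, int]  # (protein accession, 1-based center position)

    @property
    def center_residue(self) -> str:
        return self.residues[len(self.residues) // 2]


@dataclass(frozen=True)
class MotifConfig:
    half_width: int = 6
    min_occurrence: int = 10  # strict >, i.e. at least 11 foreground matches
    p_threshold: float = 1e-6
    pool_st: bool = True  # search S and T centers as one S/T class

    def __post_init__(self) -> None:
        if self.half_width < 1 or self.min_occurrence < 0 or not 0 < self.p_threshold < 1:
            raise ValueError("invalid motif configuration")


@dataclass(frozen=True)
class Motif:
    center_class: str  # "S/T", "S", "T", or "Y"
    fixed: tuple[tuple[int, str], ...]  # ((offset, residue), ...), offset != 0
    fg_matches: int  # k: foreground windows matching every fixed pair
    fg_total: int  # n: foreground size when this motif's search started
    bg_probability: float  # full-background match probability of the motif
    p_value: float  # worst (largest) per-step binomial p among fixed pairs
    fold_enrichment: float
    score: float  # sum of -log10(step p), the conventional motif score

    def pattern(self) -> str:
        """Human-readable pattern, e.g. 'R-x-x-pS/pT'."""
        center = "/".join("p" + c for c in self.center_class.split("/"))
        offsets = [off for off, _ in self.fixed]
        lo = min(offsets + [0])
        hi = max(offsets + [0])
        fixed_map = dict((off, res) for off, res in self.fixed)
        parts = []
        for off in range(lo, hi + 1):
            if off == 0:
                parts.append(center)
            else:
                parts.append(fixed_map.get(off, "x"))
        return "-".join(parts)


def extract_windows(
    proteome: dict[str, str],
    sites: list[tuple[str, int]],
    half_width: int = 6,
) -> list[Window]:
    """One padded window per unique (protein, position) phosphosite.

    Sites whose residue is not S/T/Y are skipped with a warning.
    """
    windows: list[Window] = []
    seen: set[tuple[str, int]] = set()
    for accession, pos in sites:
        if (accession, pos) in seen:
            continue
        seen.add((accession, pos))
        seq = proteome[accession]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"site position {pos} outside {accession} (length {len(seq)})")
        if seq[pos - 1] not in "STY":
            logger.warning("skipping non-S/T/Y site %s:%d (%s)", accession, pos, seq[pos - 1])
            continue
        start = pos - 1 - half_width
        end = pos + half_width
        left_pad = max(0, -start)
        right_pad = max(0, end - len(seq))
        chunk = seq[max(0, start) : min(len(seq), end)]
        windows.append(
            Window(residues=PAD * left_pad + chunk + PAD * right_pad, origin=(accession, pos))
        )
    return windows


def background_windows(proteome: dict[str, str], half_width: int = 6) -> list[Window]:
    """One window per S/T/Y occurrence in every protein of the proteome."""
    sites = [
        (accession, i + 1)
        for accession, seq in proteome.items()
        for i, ch in enumerate(seq)
        if ch in "STY"
    ]
    return extract_windows(proteome, sites, half_width)


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), computed stably for large n."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _encode(windows: list[Window], width: int) -> np.ndarray:
    """Windows as an (n, width) int8 matrix; pad and unknown letters are -1."""
    mat = np.full((len(windows), width), -1, dtype=np.int8)
    for i, w in enumerate(windows):
        for j, ch in enumerate(w.residues):
            mat[i, j] = _AA_INDEX.get(ch, -1)
    return mat


def motif_match(window: Window, motif: Motif) -> bool:
    """True iff the center residue is in the motif's class and every fixed
    (offset, residue) pair matches; the pad character never matches."""
    half = len(window.residues) // 2
    if window.center_residue not in motif.center_class.split("/"):
        return False
    for off, res in motif.fixed:
        j = half + off
        if j < 0 or j >= len(window.residues) or window.residues[j] != res:
            return False
    return True


def _class_members(center_class: str) -> tuple[str, ...]:
    return tuple(center_class.split("/"))


def run_motifx(
    foreground_windows: list[Window],
    background_windows: list[Window],
    config: MotifConfig = MotifConfig(),
) -> list[Motif]:
    """Iterative motif extraction per center class; deterministic given inputs.

    Tie-breaking when fixing a pair: smallest p, then largest count, then
    smallest |offset|, then alphabetical residue.
    """
    if not foreground_windows:
        return []
    width = 2 * config.half_width + 1
    for w in foreground_windows + background_windows:
        if len(w.residues) != width:
            raise ValueError("window width does not match configuration")

    classes = ["S/T", "Y"] if config.pool_st else ["S", "T", "Y"]
    motifs: list[Motif] = []
    for center_class in classes:
        members = _class_members(center_class)
        fg = [w for w in foreground_windows if w.center_residue in members]
        bg = [w for w in background_windows if w.center_residue in members]
        if not fg or not bg:
            continue
        fg_mat = _encode(fg, width)
        bg_mat = _encode(bg, width)
        motifs.extend(_search_class(center_class, fg_mat, bg_mat, config))
    return motifs


def _pair_counts(mat: np.ndarray, width: int) -> np.ndarray:
    """(width, 20) matrix of residue counts per offset column."""
    counts = np.zeros((width, len(AMINO_ACIDS)), dtype=np.int64)
    for j in range(width):
        col = mat[:, j]
        valid = col[col >= 0]
        if len(valid):
            counts[j] = np.bincount(valid, minlength=len(AMINO_ACIDS))
    return counts


def _search_class(
    center_class: str, fg_mat: np.ndarray, bg_mat: np.ndarray, config: MotifConfig
) -> list[Motif]:
    width = fg_mat.shape[1]
    center = width // 2
    full_bg = bg_mat
    motifs: list[Motif] = []
    pool = fg_mat
    while len(pool):
        n0 = len(pool)
        fg = pool
        bg = full_bg
        fixed: list[tuple[int, str]] = []
        step_ps: list[float] = []
        fixed_offsets: set[int] = set()
        while True:
            best = None  # (p, -k, |offset|, residue, offset, aa_idx)
            fg_counts = _pair_counts(fg, width)
            bg_counts = _pair_counts(bg, width)
            fg_valid = (fg >= 0).sum(axis=0)
            bg_valid = (bg >= 0).sum(axis=0)
            for j in range(width):
                if j == center or j - center in fixed_offsets:
                    continue
                n = int(fg_valid[j])
                m = int(bg_valid[j])
                if n == 0 or m == 0:
                    continue
                for a in range(len(AMINO_ACIDS)):
                    k = int(fg_counts[j, a])
                    if k <= config.min_occurrence:
                        continue
                    p0 = bg_counts[j, a] / m
                    p = binomial_upper_tail(k, n, p0)
                    if p >= config.p_threshold:
                        continue
                    key = (p, -k, abs(j - center), AMINO_ACIDS[a])
                    if best is None or key < best[0]:
                        best = (key, j - center, a)
            if best is None:
                break
            (p, neg_k, _absoff, residue), offset, aa_idx = best
            fixed.append((offset, residue))
            fixed_offsets.add(offset)
            step_ps.append(p)
            j = offset + center
            fg = fg[fg[:, j] == aa_idx]
            bg = bg[bg[:, j] == aa_idx]
        if not fixed:
            break
        fixed_t = tuple(sorted(fixed))
        k_final = len(fg)
        # motif-level background probability over the full background
        mask = np.ones(len(full_bg), dtype=bool)
        for off, res in fixed_t:
            mask &= full_bg[:, off + center] == _AA_INDEX[res]
        p0_motif = float(mask.sum()) / len(full_bg)
        fold = (k_final / n0) / p0_motif if p0_motif > 0 else float("inf")
        motifs.append(
            Motif(
                center_class=center_class,
                fixed=fixed_t,
                fg_matches=k_final,
                fg_total=n0,
                bg_probability=p0_motif,
                p_value=max(step_ps),
                fold_enrichment=fold,
                score=float(sum(-np.log10(max(p, 1e-300)) for p in step_ps)),
            )
        )
        # remove windows matching every fixed pair from the pool and restart
        matched = np.ones(len(pool), dtype=bool)
        for off, res in fixed_t:
            matched &= pool[:, off + center] == _AA_INDEX[res]
        pool = pool[~matched]
    return motifs
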