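"""Ortholog-group parsing and best-hit group assignment.

Reference species (here Arabidopsis and rice) come with precomputed
OrthoMCL-style groups; a further species (soybean) is classified by protein
similarity: each query inherits the ortholog group of its lowest-E-value
hit among the reference proteins, with hits admitted only below a strict
E-value threshold (default 1e-5).

Two similarity backends feed the same assignment rule:

* ``internal`` — Smith-Waterman local alignment (affine gaps, BLOSUM62)
  with Karlin-Altschul bit scores and E-values, suitable for desk-scale
  datasets and fully deterministic. A shared-k-mer prescreen (BLAST-like
  seeding) keeps the number of alignments per query small.
* ``tabular`` — a precomputed 12-column BLAST tabular (outfmt 6) file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .quant_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityParams:
    """Scoring parameters for the internal alignment backend.

    Karlin-Altschul lambda/K default to the standard gapped BLOSUM62 values.
    The unknown residue X scores 0 against everything.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0  # first gap residue costs gap_open + gap_extend
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0 or self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("similarity parameters must be positive")


@lru_cache(maxsize=8)
def _matrix(name: str):
    mat = substitution_matrices.load(name).copy()
    if "X" in mat.alphabet:
        for ch in mat.alphabet:
            mat["X", ch] = 0.0
            mat[ch, "X"] = 0.0
    return mat


def make_aligner(params: SimilarityParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        substitution_matrix=_matrix(params.matrix_name),
        open_gap_score=-(params.gap_open + params.gap_extend),
        extend_gap_score=-params.gap_extend,
        mode=mode,
    )
    return aligner


def smith_waterman_score(seq_a: str, seq_b: str, params: SimilarityParams = SimilarityParams()) -> float:
    """Optimal local alignment score with affine gaps."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    return float(make_aligner(params, "local").score(seq_a, seq_b))


def karlin_altschul_evalue(
    raw_score: float, len_query: int, len_subject: int, params: SimilarityParams = SimilarityParams()
) -> tuple[float, float]:
    """(bit_score, e_value): bits = (lambda*S - ln K)/ln 2; E = m*n*2^-bits."""
    if len_query <= 0 or len_subject <= 0:
        raise ValueError("sequence lengths must be positive")
    bits = (params.ka_lambda * raw_score - math.log(params.ka_k)) / math.log(2.0)
    evalue = float(len_query) * float(len_subject) * math.pow(2.0, -bits)
    return bits, evalue


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    raw_score: float | None
    bit_score: float
    e_value: float
    backend: str  # "internal" | "tabular"


@dataclass
class OrthologGroupTable:
    """OrthoMCL-style groups: group id -> (species, accession) members."""

    groups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    accession_to_group: dict[str, str] = field(default_factory=dict)

    def members(self, group_id: str, species: str | None = None) -> list[str]:
        out = self.groups.get(group_id, [])
        return [acc for sp, acc in out if species is None or sp == species]

    def species_with_member(self, group_id: str) -> set[str]:
        return {sp for sp, _acc in self.groups.get(group_id, [])}

    def add(self, group_id: str, species: str, accession: str) -> None:
        if accession in self.accession_to_group:
            raise ValueError(
                f"accession {accession} appears in both "
                f"{self.accession_to_group[accession]} and {group_id}"
            )
        self.groups.setdefault(group_id, []).append((species, accession))
        self.accession_to_group[accession] = group_id


def read_groups(path: str | Path) -> OrthologGroupTable:
    """Parse an OrthoMCL groups text file: 'GROUP_ID: taxon|acc taxon|acc ...'."""
    table = OrthologGroupTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing ':' group separator")
            group_id, rest = line.split(":", 1)
            group_id = group_id.strip()
            members = rest.split()
            if not group_id or not members:
                raise ValueError(f"{path}:{lineno}: malformed group line")
            for token in members:
                if "|" not in token:
                    raise ValueError(f"{path}:{lineno}: malformed member token {token!r}")
                species, accession = token.split("|", 1)
                table.add(group_id, species, accession)
    return table


def write_groups(table: OrthologGroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for group_id in sorted(table.groups):
            members = " ".join(f"{sp}|{acc}" for sp, acc in table.groups[group_id])
            fh.write(f"{group_id}: {members}\n")


def read_blast_tabular(path: str | Path) -> list[SimilarityHit]:
    """Read 12-column BLAST outfmt-6: E-value in column 11, bit score in 12."""
    df = pd.read_csv(path, sep="\t", header=None, float_precision="round_trip")
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, found {df.shape[1]}")
    return [
        SimilarityHit(
            query=str(row[0]),
            subject=str(row[1]),
            raw_score=None,
            bit_score=float(row[11]),
            e_value=float(row[10]),
            backend="tabular",
        )
        for row in df.itertuples(index=False)
    ]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass(frozen=True)
class Assignment:
    query: str
    group_id: str | None
    best_hit: SimilarityHit | None


def _internal_hits(
    query: ProteinRecord,
    references: list[ProteinRecord],
    ref_kmers: dict[str, set[str]],
    params: SimilarityParams,
    seed_kmers: int,
    max_candidates: int,
) -> list[SimilarityHit]:
    qk = _kmer_set(query.sequence, 4)
    scored = []
    for ref in references:
        shared = len(qk & ref_kmers[ref.accession])
        if shared >= seed_kmers:
            scored.append((shared, ref))
    scored.sort(key=lambda t: (-t[0], t[1].accession))
    hits = []
    for _shared, ref in scored[:max_candidates]:
        raw = smith_waterman_score(query.sequence, ref.sequence, params)
        bits, evalue = karlin_altschul_evalue(raw, len(query.sequence), len(ref.sequence), params)
        hits.append(
            SimilarityHit(
                query=query.accession,
                subject=ref.accession,
                raw_score=raw,
                bit_score=bits,
                e_value=evalue,
                backend="internal",
            )
        )
    return hits


def assign_best_hit(
    query_proteins: list[ProteinRecord],
    reference_proteins: list[ProteinRecord],
    group_table: OrthologGroupTable,
    params: SimilarityParams = SimilarityParams(),
    e_threshold: float = 1e-5,
    hits: list[SimilarityHit] | None = None,
    seed_kmers: int = 8,
    max_candidates: int = 25,
) -> dict[str, Assignment]:
    """Assign each query to the ortholog group of its lowest-E-value hit.

    Only hits with E strictly below ``e_threshold`` qualify; ties on E are
    broken by higher bit score, then lexicographically smallest subject.
    Queries with no qualifying hit (or whose best subject carries no group)
    are left unassigned. With a precomputed ``hits`` list, no alignment is
    run; hits naming unknown accessions are dropped with a warning.
    """
    known_queries = {q.accession for q in query_proteins}
    known_refs = {r.accession for r in reference_proteins}
    by_query: dict[str, list[SimilarityHit]] = {q.accession: [] for q in query_proteins}

    if hits is not None:
        for h in hits:
            if h.query not in known_queries or h.subject not in known_refs:
                logger.warning("dropping hit with unknown accession: %s -> %s", h.query, h.subject)
                continue
            by_query[h.query].append(h)
    else:
        ref_kmers = {r.accession: _kmer_set(r.sequence, 4) for r in reference_proteins}
        for q in sorted(query_proteins, key=lambda p: p.accession):
            by_query[q.accession] = _internal_hits(
                q, reference_proteins, ref_kmers, params, seed_kmers, max_candidates
            )

    assignments: dict[str, Assignment] = {}
    for q in sorted(known_queries):
        qualifying = [h for h in by_query[q] if h.e_value < e_threshold]
        if not qualifying:
            assignments[q] = Assignment(query=q, group_id=None, best_hit=None)
            continue
        best = min(qualifying, key=lambda h: (h.e_value, -h.bit_score, h.subject))
        group_id = group_table.accession_to_group.get(best.subject)
        assignments[q] = Assignment(query=q, group_id=group_id, best_hit=best)
    return assignments


def assignments_to_frame(assignments: dict[str, Assignment]) -> pd.DataFrame:
    rows = []
    for q in sorted(assignments):
        a = assignments[q]
        rows.append(
            {
                "query": q,
                "group_id": a.group_id or "",
                "subject": a.best_hit.subject if a.best_hit else "",
                "e_value": a.best_hit.e_value if a.best_hit else "",
                "bit_score": a.best_hit.bit_score if a.best_hit else "",
                "backend": a.best_hit.backend if a.best_hit else "",
            }
        )
    return pd.DataFrame(rows, columns=["query", "group_id", "subject", "e_value", "bit_score", "backend"])
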