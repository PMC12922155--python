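"""Cross-species conservation of ABA-responsive phosphorylation.

Three layers of accounting:

* protein level — for a reference species, how many of its responsive
  phosphoproteins have an ortholog in each other species, and how many of
  those orthologs are themselves responsive (the red/pink/gray matrix).
  All rates are expressed over the reference species' responsive-protein
  count, matching the printed arithmetic of the source tables.
* group level — per-species sets of responsive ortholog groups and the
  seven regions of their 3-set Venn (regions tagged A..G: A = all three
  species, B/C/D = exactly two, E/F/G = species-specific).
* site level — phosphosite coordinates transferred through pairwise global
  alignments between ortholog members and classified as conserved-responsive,
  conserved-residue-only, position-not-conserved, or unalignable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._util import percent
from .ortholog_mapping import (
    OrthologGroupTable,
    SimilarityParams,
    karlin_altschul_evalue,
    make_aligner,
)

logger = logging.getLogger(__name__)

CATEGORY_CONSERVED_RESPONSIVE = "conserved-responsive"
CATEGORY_CONSERVED_RESIDUE = "conserved-residue-only"
CATEGORY_NOT_CONSERVED = "position-not-conserved"
CATEGORY_UNALIGNABLE = "unalignable"


# ---------------------------------------------------------------------------
# group-level accounting


def responsive_group_sets(
    membership: dict[str, dict[str, str]],
    responsive_proteins: dict[str, list[str]],
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-species sets of ortholog groups containing >=1 responsive protein.

    ``membership`` maps species -> accession -> group id (reference species
    from the groups table, additional species from best-hit assignment).
    Returns the group sets and, per species, the number of responsive
    proteins without any group ("no ortholog" tally).
    """
    sets: dict[str, set[str]] = {}
    no_group: dict[str, int] = {}
    for species, proteins in responsive_proteins.items():
        acc_to_group = membership.get(species, {})
        groups = set()
        missing = 0
        for acc in proteins:
            g = acc_to_group.get(acc)
            if g is None:
                missing += 1
            else:
                groups.add(g)
        sets[species] = groups
        no_group[species] = missing
    return sets, no_group


@dataclass(frozen=True)
class ConservationMatrix:
    """Per reference species, ortholog presence/responsiveness counts.

    ``per_target`` maps target species -> (n_with_ortholog,
    n_ortholog_responsive); ``rates`` holds the same as percentages of
    ``n_responsive`` to one decimal.
    """

    reference_species: str
    n_responsive: int
    per_target: dict[str, tuple[int, int]]
    rates: dict[str, tuple[float, float]]


def conservation_matrix(
    reference_species: str,
    responsive_proteins: dict[str, list[str]],
    membership: dict[str, dict[str, str]],
    group_presence: dict[str, set[str]],
    responsive_groups: dict[str, set[str]],
) -> ConservationMatrix:
    """Count, per target species, reference responsive proteins whose group
    has a member in the target (has ortholog) and whose group is responsive
    in the target (ortholog responsive).

    ``group_presence`` maps species -> groups with >=1 member of that species
    (reference species from the table, assigned species from assignments).
    """
    ref_responsive = sorted(set(responsive_proteins[reference_species]))
    acc_to_group = membership.get(reference_species, {})
    n_ref = len(ref_responsive)
    per_target: dict[str, tuple[int, int]] = {}
    rates: dict[str, tuple[float, float]] = {}
    for target in sorted(group_presence):
        if target == reference_species:
            continue
        with_orth = 0
        orth_resp = 0
        for acc in ref_responsive:
            g = acc_to_group.get(acc)
            if g is None:
                continue
            if g in group_presence[target]:
                with_orth += 1
                if g in responsive_groups.get(target, set()):
                    orth_resp += 1
        per_target[target] = (with_orth, orth_resp)
        if n_ref > 0:
            rates[target] = (percent(with_orth, n_ref), percent(orth_resp, n_ref))
        else:
            rates[target] = (0.0, 0.0)
    return ConservationMatrix(
        reference_species=reference_species,
        n_responsive=n_ref,
        per_target=per_target,
        rates=rates,
    )


REGION_TAGS = ("A", "B", "C", "D", "E", "F", "G")


@dataclass(frozen=True)
class GroupVenn:
    """3-set Venn of responsive ortholog groups.

    Region tags follow the source convention for species order
    (s1, s2, s3): A = triple intersection, B = s1&s2 only, C = s1&s3 only,
    D = s2&s3 only, E/F/G = specific to s1/s2/s3.
    """

    species: tuple[str, str, str]
    regions: dict[str, frozenset[str]]

    def counts(self) -> dict[str, int]:
        return {tag: len(self.regions[tag]) for tag in REGION_TAGS}

    def species_total(self, sp: str) -> int:
        i = self.species.index(sp)
        tags = {
            0: ("A", "B", "C", "E"),
            1: ("A", "B", "D", "F"),
            2: ("A", "C", "D", "G"),
        }[i]
        return sum(len(self.regions[t]) for t in tags)

    def pairwise_overlap_pct(self, reference: str, other: str) -> float:
        """|reference ∩ other| as a percentage of the reference total."""
        sets = self._sets()
        inter = len(sets[reference] & sets[other])
        return percent(inter, len(sets[reference]))

    def _sets(self) -> dict[str, set[str]]:
        s1, s2, s3 = self.species
        return {
            s1: set().union(*(self.regions[t] for t in ("A", "B", "C", "E"))),
            s2: set().union(*(self.regions[t] for t in ("A", "B", "D", "F"))),
            s3: set().union(*(self.regions[t] for t in ("A", "C", "D", "G"))),
        }


def venn_counts(group_sets: dict[str, set[str]]) -> GroupVenn:
    """All 7 region sets of the 3-set Venn over responsive group ids."""
    if len(group_sets) != 3:
        raise ValueError("venn_counts requires exactly three species")
    s1, s2, s3 = list(group_sets)
    a, b, c = group_sets[s1], group_sets[s2], group_sets[s3]
    regions = {
        "A": frozenset(a & b & c),
        "B": frozenset((a & b) - c),
        "C": frozenset((a & c) - b),
        "D": frozenset((b & c) - a),
        "E": frozenset(a - b - c),
        "F": frozenset(b - a - c),
        "G": frozenset(c - a - b),
    }
    return GroupVenn(species=(s1, s2, s3), regions=regions)


# ---------------------------------------------------------------------------
# site-level mapping


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings plus scores."""

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float
    bit_score: float

    def column_of_a(self, position_in_a: int) -> int:
        """Alignment column index (0-based) holding seq_a position (1-based)."""
        if not 1 <= position_in_a <= len(self.seq_a):
            raise ValueError(f"position {position_in_a} outside sequence of length {len(self.seq_a)}")
        count = 0
        for col, ch in enumerate(self.aligned_a):
            if ch != "-":
                count += 1
                if count == position_in_a:
                    return col
        raise AssertionError("unreachable: alignment shorter than sequence")


def needleman_wunsch_align(
    seq_a: str, seq_b: str, params: SimilarityParams = SimilarityParams()
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (same scoring as the local
    aligner); the first-reported optimal traceback is used, which is
    deterministic for fixed inputs."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aligner = make_aligner(params, "global")
    aln = aligner.align(seq_a, seq_b)[0]
    bits, _e = karlin_altschul_evalue(aln.score, len(seq_a), len(seq_b), params)
    return PairwiseAlignment(
        seq_a=seq_a,
        seq_b=seq_b,
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        bit_score=bits,
    )


def map_site(alignment: PairwiseAlignment, position_in_a: int) -> tuple[int | None, str | None]:
    """Transfer a 1-based coordinate in seq_a to seq_b through the alignment.

    Returns (position_in_b, residue_in_b), or (None, None) when the site
    falls on a gap column in seq_b.
    """
    col = alignment.column_of_a(position_in_a)
    if alignment.aligned_b[col] == "-":
        return None, None
    pos_b = sum(1 for ch in alignment.aligned_b[: col + 1] if ch != "-")
    return pos_b, alignment.seq_b[pos_b - 1]


def classify_site(
    alignment: PairwiseAlignment,
    position_in_a: int,
    partner_responsive_sites: set[int],
    bit_floor: float = 25.0,
) -> str:
    """Classify conservation of one phosphosite against the ortholog partner.

    conserved-responsive: maps onto a responsive phosphosite in the partner;
    conserved-residue-only: maps onto S/T/Y that is not responsive;
    position-not-conserved: maps onto a non-S/T/Y residue or a gap;
    unalignable: the pair's alignment bit score is below ``bit_floor``.
    """
    if alignment.bit_score < bit_floor:
        return CATEGORY_UNALIGNABLE
    pos_b, res_b = map_site(alignment, position_in_a)
    if pos_b is None or res_b not in ("S", "T", "Y"):
        return CATEGORY_NOT_CONSERVED
    if pos_b in partner_responsive_sites:
        return CATEGORY_CONSERVED_RESPONSIVE
    return CATEGORY_CONSERVED_RESIDUE


@dataclass(frozen=True)
class SiteMapping:
    group_id: str
    species_a: str
    accession_a: str
    position_a: int
    species_b: str
    accession_b: str
    position_b: int | None
    residue_b: str | None
    category: str


def best_partner(
    seq_a: str,
    candidates: dict[str, str],
    params: SimilarityParams = SimilarityParams(),
) -> tuple[str, PairwiseAlignment] | None:
    """Within a group that may contain paralogs, pick the partner with the
    highest alignment bit score (ties by accession)."""
    best: tuple[str, PairwiseAlignment] | None = None
    for acc in sorted(candidates):
        aln = needleman_wunsch_align(seq_a, candidates[acc], params)
        if best is None or aln.bit_score > best[1].bit_score:
            best = (acc, aln)
    return best


def map_group_sites(
    group_id: str,
    species_a: str,
    accession_a: str,
    seq_a: str,
    sites_a: list[int],
    species_b: str,
    partner_seqs: dict[str, str],
    partner_responsive_sites: dict[str, set[int]],
    params: SimilarityParams = SimilarityParams(),
    bit_floor: float = 25.0,
) -> list[SiteMapping]:
    """Map and classify every responsive site of one protein against the best
    ortholog partner in another species."""
    chosen = best_partner(seq_a, partner_seqs, params)
    if chosen is None:
        return []
    acc_b, aln = chosen
    out = []
    for pos in sorted(sites_a):
        category = classify_site(aln, pos, partner_responsive_sites.get(acc_b, set()), bit_floor)
        pos_b, res_b = (None, None) if category == CATEGORY_UNALIGNABLE else map_site(aln, pos)
        out.append(
            SiteMapping(
                group_id=group_id,
                species_a=species_a,
                accession_a=accession_a,
                position_a=pos,
                species_b=species_b,
                accession_b=acc_b,
                position_b=pos_b,
                residue_b=res_b,
                category=category,
            )
        )
    return out
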