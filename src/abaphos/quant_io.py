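"""Phosphopeptide quantification tables, proteome FASTA, and dataset summaries.

The quantification table is a TSV with one row per quantified phosphopeptide:

    peptide_id  bare_sequence  protein_accession  sites  t0_r1 ... t90_r3

``sites`` is a semicolon-joined list of residue+position tokens on the
*protein* coordinate system (1-based), e.g. ``S173;S177``. Abundance cells are
linear-scale label-free intensities; blank means missing (never zero).

Dataset-level summaries mirror the standard overview of a phosphoproteomic
experiment: enrichment efficiency (phosphopeptide fraction of all identified
peptides), the pS/pT/pY residue distribution, and phosphosite multiplicity
per peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._util import percent, round_half_away

logger = logging.getLogger(__name__)

TIMEPOINTS = (0, 15, 30, 90)
REPLICATES = (1, 2, 3)
ABUNDANCE_COLUMNS = tuple(f"t{t}_r{r}" for t in TIMEPOINTS for r in REPLICATES)
TABLE_COLUMNS = ("peptide_id", "bare_sequence", "protein_accession", "sites") + ABUNDANCE_COLUMNS

PHOSPHO_RESIDUES = ("S", "T", "Y")


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry; accession is the first whitespace token of the header."""

    accession: str
    species: str
    sequence: str


@dataclass
class PhosphoPeptide:
    """A quantified phosphopeptide with localized sites.

    ``sites`` holds (1-based position in the protein, residue) pairs;
    ``abundances`` maps (timepoint_min, replicate) to a linear intensity or
    None for missing.
    """

    peptide_id: str
    bare_sequence: str
    protein_accession: str
    species: str
    sites: list[tuple[int, str]]
    abundances: dict[tuple[int, int], float | None] = field(default_factory=dict)

    @property
    def multiplicity(self) -> int:
        return len(self.sites)

    def condition(self, timepoint: int) -> list[float]:
        """Non-missing replicate abundances at one timepoint."""
        return [
            v
            for (t, _r), v in sorted(self.abundances.items())
            if t == timepoint and v is not None
        ]


@dataclass(frozen=True)
class DatasetSummary:
    species: str
    n_peptides_total: int | None
    n_phosphopeptides: int
    n_proteins: int
    residue_fractions: tuple[float, float, float]
    multiplicity_fractions: tuple[float, float, float]
    enrichment_efficiency_pct: int | None


def read_proteome(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a proteome FASTA; uppercase sequences, strip stop '*' characters."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise ValueError(f"duplicate accession in {path}: {accession}")
        seen.add(accession)
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise ValueError(f"empty sequence for {accession} in {path}")
        records.append(ProteinRecord(accession=accession, species=species, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def write_proteome(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def proteome_index(records: list[ProteinRecord]) -> dict[str, str]:
    return {r.accession: r.sequence for r in records}


def parse_sites(token: str) -> list[tuple[int, str]]:
    """Parse 'S173;S177' into [(173, 'S'), (177, 'S')]."""
    sites = []
    for part in str(token).split(";"):
        part = part.strip()
        if not part:
            continue
        residue, pos_str = part[0], part[1:]
        if residue not in PHOSPHO_RESIDUES or not pos_str.isdigit() or int(pos_str) < 1:
            raise ValueError(f"malformed site token: {part!r}")
        sites.append((int(pos_str), residue))
    if not sites:
        raise ValueError(f"no sites parsed from {token!r}")
    return sites


def format_sites(sites: list[tuple[int, str]]) -> str:
    return ";".join(f"{res}{pos}" for pos, res in sites)


def read_phosphopeptide_table(
    path: str | Path,
    species: str,
    proteome: list[ProteinRecord] | dict[str, str] | None = None,
    rejects_path: str | Path | None = None,
) -> list[PhosphoPeptide]:
    """Read a quantification TSV; rows failing the proteome cross-check are
    quarantined to a sidecar rejects TSV instead of aborting the run.

    Site residues are validated against the protein sequence when a proteome
    is supplied; a mismatch or out-of-bounds position rejects the row with a
    warning. Malformed site tokens are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str}, keep_default_na=False)
    missing_cols = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")

    seqs = proteome if proteome is None or isinstance(proteome, dict) else proteome_index(proteome)
    peptides: list[PhosphoPeptide] = []
    rejects: list[tuple[pd.Series, str]] = []
    for _, row in df.iterrows():
        sites = parse_sites(row["sites"])  # malformed -> hard error
        reason = None
        if seqs is not None:
            seq = seqs.get(row["protein_accession"])
            if seq is None:
                reason = "unknown protein accession"
            else:
                for pos, res in sites:
                    if pos > len(seq):
                        reason = f"site {res}{pos} beyond protein length {len(seq)}"
                        break
                    if seq[pos - 1] != res:
                        reason = f"site {res}{pos} mismatches protein residue {seq[pos - 1]}"
                        break
        if reason is not None:
            logger.warning("quarantined %s: %s", row["peptide_id"], reason)
            rejects.append((row, reason))
            continue
        abundances: dict[tuple[int, int], float | None] = {}
        for t in TIMEPOINTS:
            for r in REPLICATES:
                cell = row[f"t{t}_r{r}"]
                abundances[(t, r)] = None if cell == "" else float(cell)
        peptides.append(
            PhosphoPeptide(
                peptide_id=str(row["peptide_id"]),
                bare_sequence=str(row["bare_sequence"]),
                protein_accession=str(row["protein_accession"]),
                species=species,
                sites=sites,
                abundances=abundances,
            )
        )
    if rejects:
        logger.warning("%d of %d rows quarantined from %s", len(rejects), len(df), path)
        if rejects_path is not None:
            rej_df = pd.DataFrame([r for r, _ in rejects])
            rej_df["reason"] = [reason for _, reason in rejects]
            rej_df.to_csv(rejects_path, sep="\t", index=False)
    return peptides


def write_phosphopeptide_table(peptides: list[PhosphoPeptide], path: str | Path) -> None:
    rows = []
    for pep in peptides:
        row = {
            "peptide_id": pep.peptide_id,
            "bare_sequence": pep.bare_sequence,
            "protein_accession": pep.protein_accession,
            "sites": format_sites(pep.sites),
        }
        for t in TIMEPOINTS:
            for r in REPLICATES:
                v = pep.abundances.get((t, r))
                row[f"t{t}_r{r}"] = "" if v is None else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def enrichment_efficiency(n_phosphopeptides: int, n_peptides_total: int) -> int:
    """Phosphopeptide fraction of all identified peptides, integer percent."""
    if n_peptides_total <= 0:
        raise ValueError("n_peptides_total must be positive")
    if not 0 <= n_phosphopeptides <= n_peptides_total:
        raise ValueError("n_phosphopeptides must lie in [0, n_peptides_total]")
    return int(round_half_away(100.0 * n_phosphopeptides / n_peptides_total, 0))


def residue_distribution(peptides: list[PhosphoPeptide]) -> tuple[float, float, float]:
    """(pS%, pT%, pY%) over all sites, each site counted once, to one decimal."""
    counts = {r: 0 for r in PHOSPHO_RESIDUES}
    for pep in peptides:
        for _pos, res in pep.sites:
            counts[res] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no phosphosites in input")
    return tuple(percent(counts[r], total) for r in PHOSPHO_RESIDUES)  # type: ignore[return-value]


def multiplicity_distribution(peptides: list[PhosphoPeptide]) -> tuple[float, float, float]:
    """(%1-site, %2-site, %>=3-site) peptides, to one decimal."""
    if not peptides:
        raise ValueError("no peptides in input")
    bins = [0, 0, 0]
    for pep in peptides:
        bins[min(pep.multiplicity, 3) - 1] += 1
    total = len(peptides)
    return tuple(percent(b, total) for b in bins)  # type: ignore[return-value]


def summarize_dataset(
    peptides: list[PhosphoPeptide], species: str, n_peptides_total: int | None = None
) -> DatasetSummary:
    return DatasetSummary(
        species=species,
        n_peptides_total=n_peptides_total,
        n_phosphopeptides=len(peptides),
        n_proteins=len({p.protein_accession for p in peptides}),
        residue_fractions=residue_distribution(peptides),
        multiplicity_fractions=multiplicity_distribution(peptides),
        enrichment_efficiency_pct=(
            None
            if n_peptides_total is None
            else enrichment_efficiency(len(peptides), n_peptides_total)
        ),
    )
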