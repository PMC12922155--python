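"""End-to-end orchestration: per-species analyses and the cross-species comparison.

``run_species`` produces, for one species, the dataset summary, the
responsiveness calls (with the responsive-protein list ready for external GO
tools), the enriched motif table, and PCA QC scores. ``run_comparison``
assigns the query species to ortholog groups, builds the conservation
matrix and the responsive-group Venn, and classifies site-level
conservation through pairwise alignments.

All outputs are plain TSV/JSON; each run directory receives a manifest with
the configuration echo and SHA-256 checksums of every artifact, so two runs
with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import dump_json, sha256_file
from . import conservation as cons
from .motif_enrichment import MotifConfig, background_windows, extract_windows, run_motifx
from .ortholog_mapping import (
    OrthologGroupTable,
    SimilarityParams,
    assign_best_hit,
    assignments_to_frame,
    read_blast_tabular,
    read_groups,
)
from .quant_io import (
    PhosphoPeptide,
    ProteinRecord,
    proteome_index,
    read_phosphopeptide_table,
    read_proteome,
    summarize_dataset,
)
from .responsiveness import (
    StatConfig,
    abundance_matrix,
    call_all,
    calls_to_frame,
    collapse_to_proteins,
    pca_qc,
    responsive_sites,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    species: tuple[str, str, str]
    proteome_paths: dict[str, str]
    table_paths: dict[str, str]
    groups_path: str
    outdir: str
    n_peptides_total: dict[str, int] = field(default_factory=dict)
    stat: StatConfig = field(default_factory=StatConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    e_threshold: float = 1e-5
    bit_floor: float = 25.0
    hits_path: str | None = None
    seed: int = 0

    @property
    def reference_species(self) -> tuple[str, str]:
        return self.species[:2]

    @property
    def query_species(self) -> str:
        return self.species[2]

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, outdir: str | Path, **overrides) -> "RunConfig":
        """Point a run at a fixture-bundle directory (see synthetic_data)."""
        import json

        bundle_dir = Path(bundle_dir)
        manifest = json.loads((bundle_dir / "manifest.json").read_text())
        species = tuple(manifest["config"]["species"])
        truth = json.loads((bundle_dir / "truth.json").read_text())
        totals = {
            sp: truth["species"][sp]["n_peptides_total"]
            for sp in species
            if sp in truth.get("species", {})
        }
        return cls(
            species=species,  # type: ignore[arg-type]
            proteome_paths={sp: str(bundle_dir / f"{sp}.fasta") for sp in species},
            table_paths={sp: str(bundle_dir / f"{sp}_phospho.tsv") for sp in species},
            groups_path=str(bundle_dir / "groups.txt"),
            outdir=str(outdir),
            n_peptides_total=totals,
            seed=manifest["config"]["seed"],
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("stat", "motif", "similarity"):
            if key in raw and isinstance(raw[key], dict):
                klass = {"stat": StatConfig, "motif": MotifConfig, "similarity": SimilarityParams}[key]
                raw[key] = klass(**raw[key])
        raw["species"] = tuple(raw["species"])
        return cls(**raw)


def load_species_data(cfg: RunConfig, species: str, rejects_path: str | Path | None = None):
    proteome = read_proteome(cfg.proteome_paths[species], species=species)
    peptides = read_phosphopeptide_table(
        cfg.table_paths[species], species, proteome=proteome, rejects_path=rejects_path
    )
    return proteome, peptides


def motif_table(motifs) -> pd.DataFrame:
    rows = [
        {
            "center_class": m.center_class,
            "fixed": "+".join(f"{off:+d}{res}" for off, res in m.fixed),
            "pattern": m.pattern(),
            "k": m.fg_matches,
            "n": m.fg_total,
            "p0": m.bg_probability,
            "p_value": m.p_value,
            "fold_enrichment": m.fold_enrichment,
            "score": m.score,
        }
        for m in motifs
    ]
    return pd.DataFrame(
        rows,
        columns=["center_class", "fixed", "pattern", "k", "n", "p0", "p_value", "fold_enrichment", "score"],
    )


def run_species(cfg: RunConfig, species: str) -> dict[str, Path]:
    """Per-species stage: summary, responsiveness calls, motifs, PCA QC."""
    outdir = Path(cfg.outdir) / species
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    proteome, peptides = load_species_data(cfg, species, rejects_path=outdir / "rejects.tsv")
    logger.info("%s: %d phosphopeptides on %d proteins", species, len(peptides), len(proteome))

    summary = summarize_dataset(peptides, species, cfg.n_peptides_total.get(species))
    dump_json(dataclasses.asdict(summary), outdir / "summary.json")
    artifacts["summary"] = outdir / "summary.json"

    calls = call_all(peptides, cfg.stat)
    calls_to_frame(calls, cfg.stat).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    artifacts["calls"] = outdir / "calls.tsv"
    responsive = collapse_to_proteins(calls)
    logger.info("%s: %d responsive peptides on %d proteins", species,
                sum(c.responsive for c in calls), len(responsive))
    (outdir / "responsive_proteins.txt").write_text("\n".join(responsive) + "\n")
    artifacts["responsive_proteins"] = outdir / "responsive_proteins.txt"

    seqs = proteome_index(proteome)
    sites = [
        (acc, pos)
        for acc, positions in sorted(responsive_sites(calls, peptides).items())
        for pos in sorted(positions)
    ]
    fg = extract_windows(seqs, sites, cfg.motif.half_width)
    bg = background_windows(seqs, cfg.motif.half_width)
    motifs = run_motifx(fg, bg, cfg.motif)
    logger.info("%s: %d enriched motifs from %d foreground windows", species, len(motifs), len(fg))
    motif_table(motifs).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    artifacts["motifs"] = outdir / "motifs.tsv"

    scores = pca_qc(abundance_matrix(peptides))
    if scores is not None:
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        artifacts["pca_scores"] = outdir / "pca_scores.tsv"

    _write_manifest(cfg, outdir, artifacts)
    return artifacts


def _species_membership(
    cfg: RunConfig, groups: OrthologGroupTable, assignments
) -> dict[str, dict[str, str]]:
    membership: dict[str, dict[str, str]] = {sp: {} for sp in cfg.species}
    for gid, members in groups.groups.items():
        for sp, acc in members:
            if sp in membership:
                membership[sp][acc] = gid
    for acc, a in assignments.items():
        if a.group_id is not None:
            membership[cfg.query_species][acc] = a.group_id
    return membership


def run_comparison(cfg: RunConfig) -> dict[str, Path]:
    """Cross-species stage: assignments, conservation matrix, Venn, sites."""
    outdir = Path(cfg.outdir) / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    data = {}
    for sp in cfg.species:
        if not Path(cfg.proteome_paths[sp]).exists() or not Path(cfg.table_paths[sp]).exists():
            raise FileNotFoundError(f"missing inputs for species {sp}")
        proteome, peptides = load_species_data(cfg, sp)
        calls = call_all(peptides, cfg.stat)
        data[sp] = {
            "proteome": proteome,
            "seqs": proteome_index(proteome),
            "peptides": peptides,
            "calls": calls,
            "responsive_proteins": collapse_to_proteins(calls),
            "responsive_sites": responsive_sites(calls, peptides),
        }

    groups = read_groups(cfg.groups_path)
    query = cfg.query_species
    references = [r for sp in cfg.reference_species for r in data[sp]["proteome"]]
    hits = read_blast_tabular(cfg.hits_path) if cfg.hits_path else None
    assignments = assign_best_hit(
        data[query]["proteome"], references, groups, cfg.similarity, cfg.e_threshold, hits=hits
    )
    assignments_to_frame(assignments).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    artifacts["assignments"] = outdir / "assignments.tsv"

    membership = _species_membership(cfg, groups, assignments)
    group_presence = {sp: set(membership[sp].values()) for sp in cfg.species}
    responsive_proteins = {sp: data[sp]["responsive_proteins"] for sp in cfg.species}
    group_sets, no_group = cons.responsive_group_sets(membership, responsive_proteins)

    matrix_rows = []
    for sp in cfg.species:
        m = cons.conservation_matrix(sp, responsive_proteins, membership, group_presence, group_sets)
        for target in m.per_target:
            with_orth, orth_resp = m.per_target[target]
            rate_orth, rate_resp = m.rates[target]
            matrix_rows.append(
                {
                    "reference": sp,
                    "target": target,
                    "n_responsive": m.n_responsive,
                    "n_with_ortholog": with_orth,
                    "n_ortholog_responsive": orth_resp,
                    "pct_with_ortholog": rate_orth,
                    "pct_ortholog_responsive": rate_resp,
                }
            )
    pd.DataFrame(matrix_rows).to_csv(outdir / "conservation_matrix.tsv", sep="\t", index=False)
    artifacts["conservation_matrix"] = outdir / "conservation_matrix.tsv"

    venn = cons.venn_counts({sp: group_sets[sp] for sp in cfg.species})
    venn_payload = {
        "species": list(venn.species),
        "region_counts": venn.counts(),
        "per_species_totals": {sp: venn.species_total(sp) for sp in cfg.species},
        "responsive_without_group": no_group,
        "regions": {tag: sorted(venn.regions[tag]) for tag in venn.regions},
    }
    dump_json(venn_payload, outdir / "venn.json")
    artifacts["venn"] = outdir / "venn.json"

    region_dir = outdir / "region_groups"
    region_dir.mkdir(exist_ok=True)
    for tag in sorted(venn.regions):
        path = region_dir / f"group_{tag}.txt"
        path.write_text("\n".join(sorted(venn.regions[tag])) + "\n")
        artifacts[f"region_{tag}"] = path

    site_rows = _site_conservation(cfg, data, membership)
    pd.DataFrame(
        site_rows,
        columns=[
            "group_id", "species_a", "accession_a", "position_a",
            "species_b", "accession_b", "position_b", "residue_b", "category",
        ],
    ).to_csv(outdir / "site_conservation.tsv", sep="\t", index=False)
    artifacts["site_conservation"] = outdir / "site_conservation.tsv"

    report = [
        "Cross-species comparison of ABA-responsive phosphorylation",
        "",
        "Responsive proteins: "
        + ", ".join(f"{sp}={len(responsive_proteins[sp])}" for sp in cfg.species),
        "Responsive ortholog groups: "
        + ", ".join(f"{sp}={venn.species_total(sp)}" for sp in cfg.species),
        f"Groups responsive in all three species (region A): {venn.counts()['A']}",
    ]
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    artifacts["report"] = outdir / "report.txt"

    _write_manifest(cfg, outdir, artifacts)
    return artifacts


def _site_conservation(cfg: RunConfig, data: dict, membership: dict) -> list[dict]:
    """Map every responsive phosphosite of every species onto its best
    ortholog partner in each other species and classify conservation."""
    group_members: dict[str, dict[str, list[str]]] = {}
    for sp in cfg.species:
        for acc, gid in membership[sp].items():
            group_members.setdefault(gid, {}).setdefault(sp, []).append(acc)

    rows = []
    for sp_a in cfg.species:
        sites_a = data[sp_a]["responsive_sites"]
        for acc_a in sorted(sites_a):
            gid = membership[sp_a].get(acc_a)
            if gid is None:
                continue
            for sp_b in cfg.species:
                if sp_b == sp_a:
                    continue
                partners = {
                    acc: data[sp_b]["seqs"][acc]
                    for acc in group_members.get(gid, {}).get(sp_b, [])
                    if acc in data[sp_b]["seqs"]
                }
                if not partners:
                    continue
                mappings = cons.map_group_sites(
                    gid,
                    sp_a,
                    acc_a,
                    data[sp_a]["seqs"][acc_a],
                    sorted(sites_a[acc_a]),
                    sp_b,
                    partners,
                    data[sp_b]["responsive_sites"],
                    cfg.similarity,
                    cfg.bit_floor,
                )
                for m in mappings:
                    rows.append(dataclasses.asdict(m))
    return rows


def _write_manifest(cfg: RunConfig, outdir: Path, artifacts: dict[str, Path]) -> None:
    # the output directory is omitted from the echo so identical runs into
    # different directories stay byte-identical
    config_echo = {k: v for k, v in dataclasses.asdict(cfg).items() if k != "outdir"}
    manifest = {
        "config": config_echo,
        "files": {path.name: sha256_file(path) for _name, path in sorted(artifacts.items())},
    }
    dump_json(manifest, outdir / "manifest.json")


def run_all(cfg: RunConfig) -> dict[str, dict[str, Path]]:
    out = {sp: run_species(cfg, sp) for sp in cfg.species}
    out["comparison"] = run_comparison(cfg)
    return out
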