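"""Self-contained three-species fixture generator with planted ground truth.

The generator emulates the statistical structure of a time-resolved,
label-free ABA phosphoproteomics experiment across three plant species:

* protein families evolved from shared ancestral sequences by i.i.d.
  substitutions and short geometric indels, written as per-species proteome
  FASTA plus an OrthoMCL-style groups file that lists the two reference
  species and withholds the third (so best-hit assignment can be tested),
  with unrelated decoy proteins and decoy groups added;
* tryptic-like phosphopeptides (cut after K/R, not before P) with
  log-normal baseline abundances over a 0/15/30/90 min x 3 replicate
  design; a planted fraction of responders is multiplied by the effect
  size from a random onset timepoint onward;
* a sequence motif written into protein sequences upstream of responsive
  phosphosites with configurable penetrance;
* planted cross-species site-conservation anchors: ancestral phosphosites
  whose partner-species residue is kept (responsive or silent) or mutated
  away, cycling through the three conservation categories.

Every random draw comes from one seeded generator; a fixed seed yields
byte-identical bundles. The planted truth (families, responders, motif
positions, anchor categories) is written alongside the data so recovery
tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._util import dump_json, sha256_file
from .quant_io import (
    REPLICATES,
    TIMEPOINTS,
    PhosphoPeptide,
    ProteinRecord,
    write_phosphopeptide_table,
    write_proteome,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# roughly plant-proteome-like composition; S/T/Y at 7.5/5.0/3.4%
AA_FREQUENCIES = np.array(
    [
        0.080, 0.015, 0.055, 0.065, 0.040, 0.070, 0.022, 0.055, 0.060, 0.095,
        0.022, 0.042, 0.048, 0.038, 0.054, 0.075, 0.050, 0.068, 0.012, 0.034,
    ]
)

CATEGORIES = ("conserved-responsive", "conserved-residue-only", "position-not-conserved")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic bundle; the defaults define
    the standard test conditions (seed 42, 200 families, 2000 peptides per
    species, 4-fold responders at log2 noise SD 0.1, 15% per-branch
    divergence, a (-3, R) motif planted at 60% penetrance)."""

    seed: int = 42
    species: tuple[str, str, str] = ("ath", "osa", "gma")
    n_families: int = 200
    family_size: int = 1
    substitution_prob: float = 0.15
    indel_rate: float = 0.005
    indel_len_p: float = 0.5
    indel_len_cap: int = 5
    protein_len_mean: float = 240.0
    protein_len_sd: float = 40.0
    protein_len_min: int = 120
    n_decoy_proteins: int = 30
    n_decoy_groups: int = 20
    n_peptides: int = 2000
    fraction_responsive: float = 0.08
    effect_size: float = 4.0
    noise_sigma: float = 0.1
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    residue_mix: tuple[float, float, float] = (0.88, 0.117, 0.003)
    multiplicity_mix: tuple[float, float, float] = (0.787, 0.173, 0.04)
    planted_motifs: tuple[tuple[tuple[tuple[int, str], ...], float], ...] = (
        (((-3, "R"),), 0.6),
    )
    missing_rate: float = 0.05
    n_anchor_families: int = 60
    onset_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    enrichment_efficiency: tuple[float, float, float] = (0.71, 0.59, 0.62)

    def __post_init__(self) -> None:
        for p in (
            self.substitution_prob,
            self.indel_rate,
            self.fraction_responsive,
            self.missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.species) != 3:
            raise ValueError("exactly three species expected")

    @property
    def reference_species(self) -> tuple[str, str]:
        return self.species[:2]

    @property
    def query_species(self) -> str:
        return self.species[2]


# ---------------------------------------------------------------------------
# family / proteome generation


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=AA_FREQUENCIES)
    return [AMINO_ACIDS[i] for i in idx]


def _substitute(rng: np.random.Generator, seq: list[str], prob: float, protect: set[int]) -> list[str]:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < prob)[0]
    for i in hits:
        if int(i) in protect:
            continue
        old = out[i]
        new = old
        while new == old:
            new = AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=AA_FREQUENCIES))]
        out[i] = new
    return out


def _geometric_len(rng: np.random.Generator, p: float, cap: int) -> int:
    return min(int(rng.geometric(p)), cap)


def _evolve(
    rng: np.random.Generator,
    ancestral: list[str],
    config: GeneratorConfig,
    protect: set[int],
    substitution_prob: float | None = None,
    indel_rate: float | None = None,
) -> tuple[list[str], list[int | None]]:
    """Mutate an ancestral sequence; returns (sequence, ancestral->new map).

    Positions within 8 residues of a protected site never receive indels so
    planted coordinates survive unambiguously.
    """
    sub_p = config.substitution_prob if substitution_prob is None else substitution_prob
    ind_r = config.indel_rate if indel_rate is None else indel_rate
    seq = _substitute(rng, ancestral, sub_p, protect)
    n = len(seq)
    n_events = rng.binomial(n, ind_r)
    event_positions = sorted(int(p) for p in rng.choice(n, size=n_events, replace=False)) if n_events else []
    events: dict[int, tuple[str, int, list[str]]] = {}
    for pos in event_positions:
        if any(abs(pos - a) <= 8 for a in protect):
            continue
        length = _geometric_len(rng, config.indel_len_p, config.indel_len_cap)
        if rng.random() < 0.5:
            events[pos] = ("del", length, [])
        else:
            events[pos] = ("ins", length, _random_sequence(rng, length))
    new_seq: list[str] = []
    anc_to_new: list[int | None] = [None] * n
    i = 0
    while i < n:
        ev = events.get(i)
        if ev is not None and ev[0] == "ins":
            new_seq.extend(ev[2])
        if ev is not None and ev[0] == "del":
            i += ev[1]
            continue
        anc_to_new[i] = len(new_seq)
        new_seq.append(seq[i])
        i += 1
    return new_seq, anc_to_new


@dataclass
class FamilyBundle:
    proteomes: dict[str, dict[str, list[str]]]  # species -> accession -> mutable sequence
    groups_lines: list[str]
    truth: dict


def generate_families(config: GeneratorConfig, rng: np.random.Generator) -> FamilyBundle:
    """Evolve ``n_families`` ancestral proteins into the three species, plant
    site-conservation anchors, and add decoy proteins/groups."""
    proteomes: dict[str, dict[str, list[str]]] = {sp: {} for sp in config.species}
    groups_lines: list[str] = []
    families: dict[str, dict[str, list[str]]] = {}
    anchors: list[dict] = []

    for fam in range(config.n_families):
        length = max(config.protein_len_min, int(rng.normal(config.protein_len_mean, config.protein_len_sd)))
        ancestral = _random_sequence(rng, length)
        anchor = None
        if fam < config.n_anchor_families:
            category = CATEGORIES[fam % len(CATEGORIES)]
            pos0 = int(rng.integers(40, length - 40))
            # engineer a clean tryptic context (K..R flanks, no internal K/R/P)
            # so the anchor peptide is always observable after digestion
            for i in range(pos0 - 7, pos0 + 8):
                if ancestral[i] in "KRP":
                    ancestral[i] = "Q"
            ancestral[pos0 - 8] = "K"
            ancestral[pos0 + 8] = "R"
            if ancestral[pos0 + 9] == "P":
                ancestral[pos0 + 9] = "A"
            ancestral[pos0] = "S"
            anchor = {"category": category, "ancestral_pos0": pos0}
        group_id = f"OG_{fam:04d}"
        fam_members: dict[str, list[str]] = {}
        member_tokens = []
        anchor_positions: dict[str, int] = {}
        anchor_residues: dict[str, str] = {}
        for sp in config.species:
            fam_members[sp] = []
            # the first species is the reference frame: it keeps the ancestral
            # sequence, so substitution_prob is the pairwise divergence of the
            # other species from it
            for m in range(config.family_size):
                first = sp == config.species[0] and m == 0
                protect = (
                    set(range(anchor["ancestral_pos0"] - 8, anchor["ancestral_pos0"] + 10))
                    if anchor
                    else set()
                )
                seq, anc_to_new = _evolve(
                    rng,
                    ancestral,
                    config,
                    protect,
                    substitution_prob=0.0 if first else None,
                    indel_rate=0.0 if first else None,
                )
                acc = f"{sp}_{fam:04d}" if config.family_size == 1 else f"{sp}_{fam:04d}_{m}"
                if anchor and m == 0:
                    new_pos = anc_to_new[anchor["ancestral_pos0"]]
                    assert new_pos is not None
                    if sp == config.species[0]:
                        residue = "S"
                    elif anchor["category"] == "position-not-conserved":
                        residue = "A"
                    else:
                        residue = "S"
                    seq[new_pos] = residue
                    anchor_positions[sp] = new_pos + 1  # 1-based
                    anchor_residues[sp] = residue
                proteomes[sp][acc] = seq
                fam_members[sp].append(acc)
                if sp in config.reference_species:
                    member_tokens.append(f"{sp}|{acc}")
        groups_lines.append(f"{group_id}: " + " ".join(member_tokens))
        families[group_id] = fam_members
        if anchor:
            anchors.append(
                {
                    "group_id": group_id,
                    "category": anchor["category"],
                    "positions": anchor_positions,
                    "residues": anchor_residues,
                    "accessions": {sp: fam_members[sp][0] for sp in config.species},
                }
            )

    decoy_groups = []
    for j in range(config.n_decoy_groups):
        group_id = f"OGD_{j:03d}"
        tokens = []
        for sp in config.reference_species:
            length = max(config.protein_len_min, int(rng.normal(config.protein_len_mean, config.protein_len_sd)))
            acc = f"{sp}_D{j:03d}"
            proteomes[sp][acc] = _random_sequence(rng, length)
            tokens.append(f"{sp}|{acc}")
        groups_lines.append(f"{group_id}: " + " ".join(tokens))
        decoy_groups.append(group_id)

    decoy_proteins: dict[str, list[str]] = {}
    for sp in config.species:
        decoy_proteins[sp] = []
        for j in range(config.n_decoy_proteins):
            length = max(config.protein_len_min, int(rng.normal(config.protein_len_mean, config.protein_len_sd)))
            acc = f"{sp}_X{j:03d}"
            proteomes[sp][acc] = _random_sequence(rng, length)
            decoy_proteins[sp].append(acc)

    truth = {
        "families": families,
        "decoy_groups": decoy_groups,
        "decoy_proteins": decoy_proteins,
        "anchors": anchors,
        "n_proteins": {sp: len(proteomes[sp]) for sp in config.species},
    }
    return FamilyBundle(proteomes=proteomes, groups_lines=groups_lines, truth=truth)


# ---------------------------------------------------------------------------
# quantification tables


def tryptic_peptides(sequence: str) -> list[tuple[int, int]]:
    """(start, end) half-open 0-based coordinates of tryptic fragments:
    cleave after K/R unless the next residue is P."""
    cuts = [0]
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1) if cuts[i + 1] > cuts[i]]


def _candidate_peptides(seqs: dict[str, list[str]]) -> list[tuple[str, int, int]]:
    out = []
    for acc in seqs:
        s = "".join(seqs[acc])
        for start, end in tryptic_peptides(s):
            if 7 <= end - start <= 35 and any(ch in "STY" for ch in s[start:end]):
                out.append((acc, start, end))
    return out


@dataclass
class _Draft:
    accession: str
    start: int
    end: int
    sites: list[int]  # 1-based protein positions
    responsive: bool
    onset: int | None
    forced_anchor: bool


def _sample_site_plan(
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> list[str]:
    """Multiplicity and residue classes for one peptide, drawn from the
    configured mixes before any peptide is chosen (so the realized mixes
    match the configuration by construction)."""
    mult_p = np.asarray(config.multiplicity_mix) / sum(config.multiplicity_mix)
    res_p = np.asarray(config.residue_mix) / sum(config.residue_mix)
    mult = int(rng.choice([1, 2, 3], p=mult_p))
    if mult == 3 and rng.random() < 0.1:
        mult = 4
    return ["STY"[int(rng.choice(3, p=res_p))] for _ in range(mult)]


def generate_quant_tables(
    config: GeneratorConfig,
    bundle: FamilyBundle,
    rng: np.random.Generator,
) -> tuple[dict[str, list[PhosphoPeptide]], dict]:
    """Sample tryptic phosphopeptides with planted responders and motifs.

    Site-conservation anchor peptides are generated first (responsive in the
    first species; responsive in the others only for the
    conserved-responsive category) and are exempt from missing-value
    injection so the planted truth remains scoreable.
    """
    tables: dict[str, list[PhosphoPeptide]] = {}
    truth: dict = {"species": {}}
    anchor_by_species: dict[str, list[dict]] = {sp: [] for sp in config.species}
    for a in bundle.truth["anchors"]:
        for sp in config.species:
            if a["residues"].get(sp) in ("S", "T", "Y"):
                anchor_by_species[sp].append(a)

    for sp_index, sp in enumerate(config.species):
        seqs = bundle.proteomes[sp]
        candidates = _candidate_peptides(seqs)
        anchor_positions = {
            (a["accessions"][sp], a["positions"][sp]) for a in anchor_by_species[sp]
        }

        drafts: list[_Draft] = []
        # forced anchor peptides
        for a in anchor_by_species[sp]:
            acc = a["accessions"][sp]
            pos = a["positions"][sp]
            region = next(
                ((s, e) for (c, s, e) in candidates if c == acc and s < pos <= e), None
            )
            if region is None:
                continue  # anchor fell in an unusable fragment; truth keeps only placed anchors
            responsive = sp_index == 0 or a["category"] == "conserved-responsive"
            drafts.append(
                _Draft(
                    accession=acc,
                    start=region[0],
                    end=region[1],
                    sites=[pos],
                    responsive=responsive,
                    onset=15 if responsive else None,
                    forced_anchor=True,
                )
            )
            a.setdefault("detected_in", []).append(sp)

        # per-candidate S/T/Y positions, excluding anchor positions
        cand_info: list[tuple[str, int, int, dict[str, list[int]]]] = []
        for acc, start, end in candidates:
            s = seqs[acc]
            by_class: dict[str, list[int]] = {"S": [], "T": [], "Y": []}
            for i in range(start, end):
                if s[i] in "STY" and (acc, i + 1) not in anchor_positions:
                    by_class[s[i]].append(i + 1)
            if any(by_class.values()):
                cand_info.append((acc, start, end, by_class))

        n_forced = len(drafts)
        n_forced_resp = sum(1 for d in drafts if d.responsive)
        n_to_sample = max(0, config.n_peptides - n_forced)
        n_resp_extra = max(0, round(config.fraction_responsive * config.n_peptides) - n_forced_resp)
        unused = [int(i) for i in rng.permutation(len(cand_info))]
        for i in range(n_to_sample):
            classes = _sample_site_plan(rng, config)
            draft = None
            while classes and draft is None:
                need = {c: classes.count(c) for c in set(classes)}
                for _attempt in range(60):
                    if unused:
                        slot = int(rng.integers(len(unused)))
                        idx = unused[slot]
                    else:  # candidate regions exhausted: allow reuse
                        slot = None
                        idx = int(rng.integers(len(cand_info)))
                    acc, start, end, by_class = cand_info[idx]
                    if all(len(by_class[c]) >= k for c, k in need.items()):
                        if slot is not None:
                            unused.pop(slot)
                        sites = []
                        for c, k in sorted(need.items()):
                            chosen = rng.choice(len(by_class[c]), size=k, replace=False)
                            sites.extend(by_class[c][int(j)] for j in chosen)
                        draft = _Draft(
                            accession=acc,
                            start=start,
                            end=end,
                            sites=sorted(sites),
                            responsive=i < n_resp_extra,
                            onset=None,
                            forced_anchor=False,
                        )
                        break
                if draft is None:
                    classes.pop()  # relax the plan; rare at realistic densities
            if draft is None:
                continue
            if draft.responsive:
                draft.onset = int(
                    rng.choice([15, 30, 90], p=np.asarray(config.onset_weights) / sum(config.onset_weights))
                )
            drafts.append(draft)

        # plant motifs into protein sequences around responsive S/T sites
        all_site_positions: dict[str, set[int]] = {}
        for d in drafts:
            all_site_positions.setdefault(d.accession, set()).update(d.sites)
        planted_motif_sites: list[list] = []
        for d in drafts:
            if not d.responsive:
                continue
            s = seqs[d.accession]
            primary = d.sites[0]
            if s[primary - 1] not in "ST":
                st = [p for p in d.sites if s[p - 1] in "ST"]
                if not st:
                    continue
                primary = st[0]
            for fixed_pairs, penetrance in config.planted_motifs:
                if rng.random() >= penetrance:
                    continue
                ok = True
                for off, res in fixed_pairs:
                    tgt = primary + off
                    if not 1 <= tgt <= len(s) or tgt in all_site_positions.get(d.accession, set()):
                        ok = False
                        break
                if not ok:
                    continue
                for off, res in fixed_pairs:
                    s[primary + off - 1] = res
                planted_motif_sites.append([d.accession, primary])

        # abundances
        peptides: list[PhosphoPeptide] = []
        effect_log2 = math.log2(config.effect_size)
        for idx, d in enumerate(drafts):
            base = config.baseline_log2_mean + rng.normal(0, config.baseline_log2_sd)
            abundances: dict[tuple[int, int], float | None] = {}
            for t in TIMEPOINTS:
                mu = base + (effect_log2 if d.responsive and d.onset is not None and t >= d.onset else 0.0)
                for r in REPLICATES:
                    value = 2.0 ** (mu + rng.normal(0, config.noise_sigma))
                    if not d.forced_anchor and rng.random() < config.missing_rate:
                        abundances[(t, r)] = None
                    else:
                        abundances[(t, r)] = value
            seq = "".join(seqs[d.accession])
            peptides.append(
                PhosphoPeptide(
                    peptide_id=f"{sp}_p{idx:05d}",
                    bare_sequence=seq[d.start : d.end],
                    protein_accession=d.accession,
                    species=sp,
                    sites=[(p, seq[p - 1]) for p in d.sites],
                    abundances=abundances,
                )
            )

        tables[sp] = peptides
        responsive_ids = [p.peptide_id for p, d in zip(peptides, drafts) if d.responsive]
        responsive_sites: dict[str, list[int]] = {}
        for p, d in zip(peptides, drafts):
            if d.responsive:
                responsive_sites.setdefault(d.accession, [])
                responsive_sites[d.accession] = sorted(set(responsive_sites[d.accession]) | set(d.sites))
        truth["species"][sp] = {
            "responsive_peptides": responsive_ids,
            "responsive_proteins": sorted({d.accession for d in drafts if d.responsive}),
            "responsive_sites": responsive_sites,
            "onsets": {
                p.peptide_id: d.onset for p, d in zip(peptides, drafts) if d.responsive
            },
            "planted_motif_sites": planted_motif_sites,
            "n_phosphopeptides": len(peptides),
            "n_peptides_total": round(len(peptides) / config.enrichment_efficiency[sp_index]),
        }
    truth["anchors"] = bundle.truth["anchors"]
    return tables, truth


# ---------------------------------------------------------------------------
# bundle writer


def write_fixture_bundle(
    config: GeneratorConfig, outdir: str | Path, overwrite: bool = False
) -> dict:
    """Generate and write the full bundle; returns the manifest dict.

    Files: one FASTA and one quant TSV per species, the groups file, the
    planted-truth JSON, and a manifest with the config echo and per-file
    SHA-256 checksums. Refuses to touch an existing bundle without
    ``overwrite``.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{outdir} already holds a bundle; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    bundle = generate_families(config, rng)
    tables, quant_truth = generate_quant_tables(config, bundle, rng)

    files: dict[str, Path] = {}
    for sp in config.species:
        records = [
            ProteinRecord(accession=acc, species=sp, sequence="".join(seq))
            for acc, seq in bundle.proteomes[sp].items()
        ]
        fasta = outdir / f"{sp}.fasta"
        write_proteome(records, fasta)
        files[f"{sp}.fasta"] = fasta
        tsv = outdir / f"{sp}_phospho.tsv"
        write_phosphopeptide_table(tables[sp], tsv)
        files[f"{sp}_phospho.tsv"] = tsv

    groups = outdir / "groups.txt"
    groups.write_text("\n".join(bundle.groups_lines) + "\n")
    files["groups.txt"] = groups

    truth = dict(bundle.truth)
    truth.update(quant_truth)
    truth_path = outdir / "truth.json"
    dump_json(truth, truth_path)
    files["truth.json"] = truth_path

    manifest = {
        "config": asdict(config),
        "files": {name: sha256_file(path) for name, path in sorted(files.items())},
    }
    dump_json(manifest, manifest_path)
    return manifest
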