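# Methods

## Scope and data model

The pipeline starts from identified, localized, MS1-quantified
phosphopeptide tables (one row per peptide + site combination, abundances
for a 0/15/30/90 min × 3 replicate design) together with per-species
proteome FASTA and an OrthoMCL-style groups file. Raw spectra, database
search, FDR control, and phosphosite localization scoring are upstream of
this package and out of scope; the table is taken as localized. Site
positions are 1-based coordinates on the full protein sequence (the "S173"
convention); peptide-internal offsets are never exposed. Missing abundance
cells are stored as missing, never as zero. Rows that contradict the
proteome (residue mismatch, out-of-range position) are quarantined to a
sidecar rejects TSV with a reason column rather than aborting the run;
malformed site tokens are hard errors. Where a peptide-group row reports
several localized sites, each reported site is counted once in the residue
and multiplicity summaries.

## Responsiveness calling

A timepoint is *testable* when both it and the baseline have ≥ 2 of 3
non-missing replicates. Fold change is the ratio of linear-scale replicate
means; the significance test is the classical pooled-variance two-sample
Student's *t*-test on log₂ intensities (Welch's form is available behind a
flag). This linear-FC / log-test split mirrors common label-free practice;
whether the original analysis tested raw or log abundances is not
documented, so the choice is recorded in `StatConfig`. A peptide is
responsive when FC > 2 (strict) and p < 0.05 (strict) at ≥ 1 of the three
post-treatment timepoints; only increases are called, and not-testable
timepoints can never satisfy the rule. No multiple-testing correction is
applied by default (raw p < α, matching the calling rule the counts
reproduce); Benjamini–Hochberg is available as an option. Zero-variance
degenerate inputs use the convention p = 1 for equal means and p = 0
otherwise. The call is invariant under global rescaling of all abundances.
PCA QC drops peptides with any missing value, column-centers the
sample × peptide matrix, and fixes component signs so the
largest-magnitude loading is positive.

## Motif enrichment

Foreground windows are the 13-mers (offsets −6…+6) around responsive
phosphosites; background windows surround every S/T/Y in the full species
proteome ("all registered genes"), not only detected proteins
(configurable). Windows overhanging a terminus are padded with `_`, which
never matches a motif and is excluded from frequency denominators —
truncated windows are kept rather than dropped so site counts stay
consistent with the number of extracted sites. S and T centers are pooled
into one S/T class (motifs are reported as pS/pT); Y is searched
separately.

The search is the canonical motif-x scheme: score every unfixed
(offset, residue) pair by the binomial upper tail of its foreground count
against the current background frequency; fix the best pair if its count
is strictly > 10 and p strictly < 10⁻⁶; reduce foreground and background
to matching windows and repeat; when no pair qualifies, emit the motif,
remove its foreground windows from the pool, restore the full background,
and restart. Background probabilities are recomputed from the reduced
background at each step. Ties are broken by smaller p, then larger count,
then smaller |offset|, then alphabetical residue — the upstream tools do
not specify a tie order, so this chain is this package's own and makes the
procedure fully deterministic. A motif's reported p-value is the largest
(least significant) of its per-step p-values; its score is the sum of
−log₁₀ p over steps; fold enrichment compares the foreground match rate
with the full-background match probability of the complete motif.

## Ortholog assignment

Reference species come from the groups file (one group per accession
enforced — grouping semantics place paralogs in the same cluster, so all
cross-species comparison is done at group level). The additional species
is assigned by best hit: among hits with E strictly < 10⁻⁵, the lowest E
wins, ties broken by higher bit score then lexicographic subject. Two
backends feed this rule: a 12-column BLAST tabular file, or the internal
aligner — Smith–Waterman with affine gaps (BLOSUM62, gap open 11, extend
1; the first gap residue costs open + extend; X scores 0 against
everything) and Karlin–Altschul statistics with standard gapped BLOSUM62
constants λ = 0.267, K = 0.041; bits = (λS − ln K)/ln 2 and
E = mn·2^(−bits) with the query × subject search space. The internal
backend prescreens candidate subjects by shared 4-mer count (a BLAST-like
seeding step, default ≥ 8 shared 4-mers, top 25 candidates) so desk-scale
datasets run in seconds; the E-value threshold, not the prescreen, decides
acceptance. The original search-engine parameters (matrix, gaps, database
composition) are not documented; only the lowest-E / E < 10⁻⁵ decision
rule is reproduced exactly, which is why an externally computed hit table
is accepted as a drop-in backend.

## Conservation accounting

The protein-level matrix counts, per reference species, responsive
proteins whose ortholog group has ≥ 1 member in the target species, and
whose group is in the target's responsive-group set. All percentages use
the reference species' responsive-protein count as denominator — including
the ortholog-responsive rates — matching the arithmetic of the published
counts (595/1137 = 52.3%, 417/944 = 44.2%). Because multiple responsive
members of one group each count once per reference protein, the accounting
is per reference protein, not per group; this is noted in the output.
Percentages are reported to one decimal, ties rounded away from zero.

Venn regions over per-species responsive group-id sets are tagged A
(all three), B/C/D (exactly two, in species order 1∩2, 1∩3, 2∩3), and
E/F/G (species-specific); pairwise overlaps are expressed over the
reference species' group total. Responsive proteins without any group are
tallied separately as "no ortholog".

Site-level conservation uses pairwise global alignment (Needleman–Wunsch,
same scoring as the local aligner) between ortholog members, not a
multiple alignment: the biological comparisons of interest are pairs of
sites in ortholog pairs, which pairwise alignment resolves
deterministically, and MSA construction is out of scope. Within a group
containing paralogs the partner with the highest alignment bit score is
used and recorded. A phosphosite maps through the alignment columns to a
partner coordinate (or gap) and is classified: conserved-responsive if
the mapped position is a responsive phosphosite of the partner;
conserved-residue-only if the mapped residue is S/T/Y but not responsive;
position-not-conserved if it maps to a non-S/T/Y residue or a gap;
unalignable if the pair's alignment scores below a bit floor (default 25
bits). The aligner's first-reported optimal traceback is used; it is
deterministic for fixed inputs.

## Synthetic data generator

The generator emulates the statistical structure of the study — it is the
package's test bed, not a simulation of mass spectrometry. Defaults define
the standard study conditions:

* **Families.** 200 ancestral proteins (length ~N(240, 40), floor 120,
  plant-like amino-acid composition with S/T/Y at 7.5/5.0/3.4%). The first
  species keeps the ancestral sequence (it is the reference frame), so the
  per-species substitution probability (default 0.15) equals the pairwise
  divergence from it; other species add geometric indels (rate 0.005 per
  residue, length geometric(0.5) capped at 5 — short, so coordinate
  mappings stay unambiguous at test divergences). The groups file lists
  the two reference species and withholds the third; 20 unrelated decoy
  groups and 30 ungrouped decoy proteins per species are added.
* **Quantification.** Tryptic-like peptides (cut after K/R, not before P,
  length 7–35, ≥ 1 S/T/Y). Multiplicity and site residue classes are drawn
  from the configured mixes (defaults 78.7/17.3/4.0% for 1/2/≥3 sites and
  88/11.7/0.3% pS/pT/pY) *before* a peptide is chosen, and a peptide
  satisfying the drawn plan is then sampled without replacement — sampling
  the plan first keeps the realized mixes at the configured values instead
  of biasing them through rejection. Baselines are log-normal
  (log₂ mean 20, SD 2, replicate noise SD 0.1); 8% of peptides are
  responders multiplied by the 4× effect from a random onset timepoint
  (weights 0.4/0.4/0.2 over 15/30/90 min, sustained thereafter, the
  typical early-and-sustained kinetics of ABA-induced phosphorylation);
  5% of cells are missing at random. An R is written at offset −3 from
  responsive S/T sites with 60% penetrance, skipping positions already
  chosen as phosphosites.
* **Site anchors.** 60 families carry one planted cross-species site
  anchor cycling through the three conservation categories. The anchor's
  tryptic context is engineered (K/R flanks, no internal K/R/P) and
  protected from substitutions and indels so the anchor peptide is always
  observable and the alignment mapping is exact; anchor peptides are
  exempt from missing-value injection so the planted categories remain
  scoreable. The partner residue is S (responsive or silent) for the
  conserved categories and A for position-not-conserved.

Every draw comes from one `numpy` generator seeded from the config; a
fixed seed yields byte-identical bundles. What the generator does *not*
model: intensity-dependent (MNAR) missingness is off by default,
peptide-level abundances are independent (no shared-protein covariance),
there is no chromatographic or charge-state structure, and decoys are
uniformly random rather than compositionally biased. Passing tests
therefore demonstrate correctness of the decision rules and statistics
under the stated noise model, not robustness to every artifact of real
LC-MS/MS data.

## Numerical choices and problem sizes

Binomial tails use the survival function of the exact binomial
distribution (stable in log space for large n); rejection-rate
calibration is checked against direct summation to 10⁻¹². Percent
reporting rounds half away from zero (integer percent for enrichment
efficiency, one decimal elsewhere). The default test and analysis scale —
200 families, 2000 peptides per species, 200-run null-motif simulations,
1000-peptide null calibrations, 200 random alignment pairs per oracle
check — was chosen so the complete analysis runs in about a minute on a
laptop-class single core while keeping every recovery estimate's sampling
error well inside the asserted margins.

## Known limitations

* The motif search follows the canonical motif-x reduction; the exact
  variant used by downstream R tooling is not documented, so per-motif
  counts may differ from other implementations on the same input even
  though the threshold semantics (k > 10, p < 10⁻⁶) are identical.
* The internal aligner is exact Smith–Waterman, not a BLAST re-implementation;
  E-values use fixed Karlin–Altschul constants rather than
  composition-adjusted statistics, so absolute E-values differ from BLAST's
  while the ranking (and hence best-hit assignment) is stable.
* Site conservation is pairwise; a residue that is unalignable pairwise
  might still be placed confidently by a profile or multiple alignment.
* GO enrichment is external by design: the pipeline exports per-region
  gene lists but computes no term statistics.
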