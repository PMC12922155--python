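#!/usr/bin/env python
"""Dataset-level overview of the three phosphoproteomes.

For each species: phosphopeptide and protein counts, enrichment
efficiency, pS/pT/pY residue distribution, and phosphosite multiplicity —
the standard first look at a phosphoproteomic experiment. Writes
results/02_dataset_summary.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from abaphos.quant_io import read_phosphopeptide_table, read_proteome, summarize_dataset

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"


def main() -> None:
    if not (BUNDLE / "manifest.json").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    truth = json.loads((BUNDLE / "truth.json").read_text())
    rows = []
    for sp in ("ath", "osa", "gma"):
        proteome = read_proteome(BUNDLE / f"{sp}.fasta", sp)
        peptides = read_phosphopeptide_table(BUNDLE / f"{sp}_phospho.tsv", sp, proteome=proteome)
        summary = summarize_dataset(peptides, sp, truth["species"][sp]["n_peptides_total"])
        rows.append(
            {
                "species": sp,
                "n_peptides_total": summary.n_peptides_total,
                "n_phosphopeptides": summary.n_phosphopeptides,
                "n_proteins": summary.n_proteins,
                "enrichment_efficiency_pct": summary.enrichment_efficiency_pct,
                "pS_pct": summary.residue_fractions[0],
                "pT_pct": summary.residue_fractions[1],
                "pY_pct": summary.residue_fractions[2],
                "mult1_pct": summary.multiplicity_fractions[0],
                "mult2_pct": summary.multiplicity_fractions[1],
                "mult3plus_pct": summary.multiplicity_fractions[2],
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "02_dataset_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nwrote results/02_dataset_summary.tsv")


if __name__ == "__main__":
    main()
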