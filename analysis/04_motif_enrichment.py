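#!/usr/bin/env python
"""Collect enriched phosphorylation motifs across the three species.

Reads the per-species motif tables produced by 03_call_responsive.py and
writes a combined table to results/04_motifs.tsv. The synthetic bundle
plants an R at offset -3 from responsive S/T sites with 60% penetrance,
so the basic kinase-style motif R-x-x-pS/pT should dominate each species.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    frames = []
    for sp in ("ath", "osa", "gma"):
        path = RUN / sp / "motifs.tsv"
        if not path.exists():
            raise SystemExit("run analysis/03_call_responsive.py first")
        df = pd.read_csv(path, sep="\t")
        df.insert(0, "species", sp)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    combined.to_csv(RESULTS / "04_motifs.tsv", sep="\t", index=False)
    print(combined[["species", "center_class", "pattern", "k", "n", "p_value", "fold_enrichment"]].to_string(index=False))
    planted = combined[combined.fixed.str.contains("-3R", na=False)]
    print(f"\nplanted R-x-x-pS/pT motif recovered in {planted.species.nunique()}/3 species")


if __name__ == "__main__":
    main()
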