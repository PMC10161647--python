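#!/usr/bin/env python
"""Call TEM-like and GBM-like regions in the simulated wild type.

Windows of 50 bp are tested per context against the demethylated
baselines (CG vs met1-like at p <= 1e-14; CHG/CHH vs ddcc-like at
p <= 1e-4 / 1e-8), merged within 500 bp, and classified by average level.
Writes results/regions.bed and prints recovery against the planted truth.
"""

from pathlib import Path

import pandas as pd

from gbmscan.io import read_cx_report, write_regions_bed
from gbmscan.regions import call_regions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = ROOT / "sim"
    wildtype = read_cx_report(sim / "methylome_wildtype.cx.tsv", genotype="wildtype")
    met1 = read_cx_report(sim / "methylome_met1_like.cx.tsv", genotype="met1_like")
    ddcc = read_cx_report(sim / "methylome_ddcc_like.cx.tsv", genotype="ddcc_like")
    regions = call_regions(wildtype, met1, ddcc)
    write_regions_bed(regions, ROOT / "regions.bed")

    truth = pd.read_csv(sim / "truth_regions.tsv", sep="\t")
    called = pd.Series([r.klass for r in regions]).value_counts()
    print(f"called {len(regions)} regions: {called.to_dict()}")
    frac_tem = called.get("TEM_LIKE", 0) / len(regions)
    print(f"TEM-like fraction of methylated regions: {frac_tem:.0%}")
    for klass in ("TEM_LIKE", "GBM_LIKE"):
        planted = truth[truth["klass"] == klass]
        same = [r for r in regions if r.klass == klass]
        hit = sum(
            any(
                r.interval.chrom == row.chrom
                and r.interval.start < row.end
                and row.start < r.interval.end
                for r in same
            )
            for row in planted.itertuples(index=False)
        )
        print(f"{klass}: recovered {hit}/{len(planted)} planted regions")


if __name__ == "__main__":
    main()
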