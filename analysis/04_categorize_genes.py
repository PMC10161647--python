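#!/usr/bin/env python
"""Assign called regions to gene features and build the exclusive groups.

Each gene becomes exactly one of pTEM / tssTEM / gbTEM / pGBM / tssGBM /
GBM, or is excluded (same-class regions in several features, or both
classes on one gene), or NONE. Writes results/gene_categories.tsv and
checks the planted categories are reproduced.
"""

from pathlib import Path

import pandas as pd

from gbmscan.genecontext import categorize_genes
from gbmscan.io import read_gene_annotation
from gbmscan.regions import read_regions_bed

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    regions = read_regions_bed(ROOT / "regions.bed")
    genes = read_gene_annotation(ROOT / "sim" / "genes.bed")
    calls = categorize_genes(regions, genes)
    df = pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls], "category": [c.category for c in calls]}
    )
    df.to_csv(ROOT / "gene_categories.tsv", sep="\t", index=False)
    print("gene categories:")
    print(df["category"].value_counts().to_string())

    truth = pd.read_csv(ROOT / "sim" / "truth_genes.tsv", sep="\t").set_index("gene_id")
    merged = df.set_index("gene_id").join(truth["true_category"])
    agreement = (merged["category"] == merged["true_category"]).mean()
    print(f"agreement with planted categories: {agreement:.1%}")


if __name__ == "__main__":
    main()
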