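#!/usr/bin/env python
"""Classify population gene-body methylation stability.

Per accession each gene is UM (CG <= 0.05) or GBM (CG >= 0.1) with
CHG <= 0.05 and CHH <= 0.02; across the 927-accession panel genes become
GBM_NV (> 700 accessions GBM), UM_NV (> 700 UM), IM_NV (GBM in 100-700;
interchangeable), or OTHER. Writes results/population_classes.tsv and
prints class percentages plus recovery of the planted classes.
"""

from pathlib import Path

import pandas as pd

from gbmscan.population import (
    class_percentages,
    classify_population,
    read_population_long,
    state_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    levels = read_population_long(ROOT / "sim" / "population.tsv")
    truth = pd.read_csv(ROOT / "sim" / "truth_population.tsv", sep="\t", index_col=0)
    states = state_matrix(levels["mCG"], levels["mCHG"], levels["mCHH"])
    pop = classify_population(states)
    pop.join(truth).to_csv(ROOT / "population_classes.tsv", sep="\t", index_label="gene_id")

    pct = class_percentages(pop, n_annotated=len(pop))
    print("population stability classes (percent of genes):")
    print(pct.to_string())
    accuracy = (pop["klass"] == truth["true_class"]).mean()
    print(f"agreement with planted classes: {accuracy:.1%}")


if __name__ == "__main__":
    main()
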