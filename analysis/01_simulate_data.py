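#!/usr/bin/env python
"""Generate the synthetic study data every downstream analysis consumes.

Writes to results/sim/: per-genotype CX methylation reports (wild type,
met1-like, ddcc-like, ddm1-like) for a 1 Mb genome with 100 genes and 50
TEM-like + 50 GBM planted regions (a fifth of the TEM regions each planted
at promoters, TSSs, and gene bodies), a 2200-gene expression matrix with
100 hyper + 100 sup planted interaction genes, and a 2000-gene x 927-
accession population methylation panel — plus the ground-truth tables.
"""

from pathlib import Path

from gbmscan.io import write_cx_report, write_expression_matrix, write_gene_bed
from gbmscan.population import write_population_long
from gbmscan.simulate import (
    ExpressionConfig,
    MethylomeConfig,
    PopulationConfig,
    simulate_expression,
    simulate_methylome,
    simulate_population,
)

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    m_cfg = MethylomeConfig(
        seed=SEED, tem_promoter_frac=0.2, tem_tss_frac=0.2, tem_body_frac=0.2
    )
    samples, truth = simulate_methylome(m_cfg)
    for genotype, sample in samples.items():
        write_cx_report(sample, OUT / f"methylome_{genotype}.cx.tsv")
    truth.regions.to_csv(OUT / "truth_regions.tsv", sep="\t", index=False)
    truth.gene_table.to_csv(OUT / "truth_genes.tsv", sep="\t", index=False)
    write_gene_bed(truth.genes, OUT / "genes.bed")
    print(
        f"methylomes: {len(samples)} genotypes, "
        f"{len(samples['wildtype'])} cytosines each; planted "
        f"{(truth.regions['klass'] == 'TEM_LIKE').sum()} TEM-like and "
        f"{(truth.regions['klass'] == 'GBM_LIKE').sum()} GBM regions"
    )

    e_cfg = ExpressionConfig(seed=SEED + 1)
    matrix, e_truth = simulate_expression(e_cfg)
    write_expression_matrix(matrix, OUT / "expression.tsv")
    e_truth.to_csv(OUT / "truth_expression.tsv", sep="\t")
    print(
        f"expression: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples; "
        f"planted roles: {e_truth['role'].value_counts().to_dict()}"
    )

    p_cfg = PopulationConfig(seed=SEED + 2)
    levels, p_truth = simulate_population(p_cfg)
    write_population_long(levels, OUT / "population.tsv")
    p_truth.to_csv(OUT / "truth_population.tsv", sep="\t")
    print(
        f"population: {p_cfg.n_genes} genes x {p_cfg.n_accessions} accessions; "
        f"planted classes: {p_truth['true_class'].value_counts().to_dict()}"
    )


if __name__ == "__main__":
    main()
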