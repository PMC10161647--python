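"""End-to-end pipeline on synthetic data with a planted-truth report.

Stages: simulate methylomes -> call and classify regions -> differential
methylation (wild type vs the ddm1-like mutant) -> gene categorization ->
simulate expression and call DEGs/priming categories -> simulate a
population panel and classify stability -> overlap enrichment of called
vs planted DEG sets. Every output file carries a provenance header
(package version, config hash, seed) and the run ends with a JSON summary
of planted-vs-recovered counts per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffmeth import STRONG, DiffThresholds, diff_regions
from .enrichment import overlap_enrichment
from .expression import categorize_priming, deg_test_contrast
from .genecontext import FeatureConfig, categorize_genes
from .io import write_cx_report, write_expression_matrix, write_gene_bed, write_regions_bed
from .population import class_percentages, classify_population, state_matrix
from .regions import ClassThresholds, call_regions
from .simulate import (
    ExpressionConfig,
    MethylomeConfig,
    PopulationConfig,
    simulate_expression,
    simulate_methylome,
    simulate_population,
)

log = logging.getLogger("gbmscan.pipeline")


@dataclass
class PipelineConfig:
    """Every stage's thresholds plus simulation settings and the seed."""

    seed: int = 0
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    class_thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    diff_thresholds: DiffThresholds = field(default_factory=DiffThresholds)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_perm: int = 1000
    n_annotated: int | None = None  # population universe; default: simulated genes

    def __post_init__(self):
        # one master seed fans out to the per-stage generators
        self.methylome = replace_seed(self.methylome, self.seed)
        self.expression = replace_seed(self.expression, self.seed + 1)
        self.population = replace_seed(self.population, self.seed + 2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        del d["diff_thresholds"]  # nested ContextCriteria: serialized separately
        d["diff_thresholds"] = {
            mode: {
                ctx: dataclasses.asdict(crit)
                for ctx, crit in self.diff_thresholds.for_mode(mode).items()
            }
            for mode in ("gbm", "tem", "drm2_chh")
        }
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def replace_seed(cfg, seed: int):
    return dataclasses.replace(cfg, seed=seed)


def provenance_header(config: PipelineConfig) -> str:
    return (
        f"gbmscan {__version__}\n"
        f"config_hash {config.config_hash()}\n"
        f"seed {config.seed}\n"
        f"features promoter={config.features.promoter_bp} tss_flank={config.features.tss_flank}"
    )


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, write per-stage outputs under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    log.info("stage 1: simulating methylomes")
    samples, truth = simulate_methylome(config.methylome)
    for genotype, sample in samples.items():
        write_cx_report(sample, outdir / f"methylome_{genotype}.cx.tsv")
    truth.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    truth.gene_table.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    write_gene_bed(truth.genes, outdir / "genes.bed")

    log.info("stage 2: calling regions")
    regions = call_regions(
        samples["wildtype"], samples["met1_like"], samples["ddcc_like"], config.class_thresholds
    )
    write_regions_bed(regions, outdir / "regions.bed", header=header)
    planted = truth.regions["klass"].value_counts().to_dict()
    called = pd.Series([r.klass for r in regions]).value_counts().to_dict()
    report["regions"] = {"planted": planted, "called": called}

    log.info("stage 3: differential methylation (wildtype vs ddm1)")
    gbm_regions = [r for r in regions if r.klass == "GBM_LIKE"]
    tem_regions = [r for r in regions if r.klass == "TEM_LIKE"]
    gbm_calls = diff_regions(
        gbm_regions, samples["wildtype"], samples["ddm1_like"], "gbm", config.diff_thresholds
    )
    tem_calls = diff_regions(
        tem_regions, samples["wildtype"], samples["ddm1_like"], "tem", config.diff_thresholds
    )
    diff_rows = [
        {
            "target": c.target,
            "mode": c.mode,
            "status": c.status,
            **{f"delta_{k}": v for k, v in c.delta.items()},
            **{f"p_{k}": v for k, v in c.p.items()},
        }
        for c in gbm_calls + tem_calls
    ]
    _write_tsv(pd.DataFrame(diff_rows), outdir / "diffmeth.tsv", header)
    report["diffmeth"] = {
        "gbm_strong": sum(c.status == STRONG for c in gbm_calls),
        "gbm_weak": sum(c.status != STRONG for c in gbm_calls),
        "tem_strong": sum(c.status == STRONG for c in tem_calls),
        "planted_ddm1_dependent": int(truth.regions["ddm1_dependent"].sum()),
    }

    log.info("stage 4: gene categorization")
    calls = categorize_genes(regions, truth.genes, config.features)
    cat_df = pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls], "category": [c.category for c in calls]}
    )
    _write_tsv(cat_df, outdir / "categories.tsv", header)
    report["categories"] = cat_df["category"].value_counts().to_dict()

    log.info("stage 5: expression DEG + priming")
    matrix, expr_truth = simulate_expression(config.expression)
    write_expression_matrix(matrix, outdir / "expression.tsv", header=header)
    mutant = next(g for g in config.expression.genotypes if g != "wildtype")
    deg_mock = deg_test_contrast(
        matrix, mutant, "wildtype", "mock", n_perm=config.n_perm, seed=config.seed + 10
    )
    deg_dc = deg_test_contrast(
        matrix, mutant, "wildtype", "BAsubDC", n_perm=config.n_perm, seed=config.seed + 11
    )
    priming = categorize_priming(deg_mock, deg_dc)
    deg_out = pd.DataFrame(
        {
            "p_combined_mock": deg_mock["p_combined"],
            "p_combined_BAsubDC": deg_dc["p_combined"],
            "log2_md_BAsubDC": deg_dc["log2_md"],
            "priming_category": priming,
            "planted_role": expr_truth["role"],
        }
    )
    deg_out.index.name = "gene_id"
    _write_tsv(deg_out.reset_index(), outdir / "deg.tsv", header)
    report["expression"] = {
        "planted": expr_truth["role"].value_counts().to_dict(),
        "called": priming.value_counts().to_dict(),
    }

    log.info("stage 6: population classification")
    levels, pop_truth = simulate_population(config.population)
    states = state_matrix(levels["mCG"], levels["mCHG"], levels["mCHH"])
    pop = classify_population(states)
    n_annot = config.n_annotated or len(pop)
    pct = class_percentages(pop, n_annot)
    pop_out = pop.join(pop_truth)
    pop_out.index.name = "gene_id"
    _write_tsv(pop_out.reset_index(), outdir / "popclass.tsv", header)
    report["population"] = {
        "planted": pop_truth["true_class"].value_counts().to_dict(),
        "called": pop["klass"].value_counts().to_dict(),
        "percent": pct["percent"].to_dict(),
    }

    log.info("stage 7: overlap enrichment of called vs planted DEG sets")
    universe = list(matrix.values.index)
    called_hyper = list(priming.index[priming == "DDM1_HYPER"])
    planted_hyper = list(expr_truth.index[expr_truth["role"] == "hyper"])
    if called_hyper and planted_hyper:
        enr = overlap_enrichment(called_hyper, planted_hyper, universe)
        report["enrichment"] = {
            "observed_overlap": enr.observed_overlap,
            "expected": enr.expected,
            "ratio": enr.ratio,
            "p": enr.p,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "report.json")
    return report


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)
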