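"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from gbmscan.io import MethylomeSample
from gbmscan.simulate import (
    MethylomeConfig,
    PopulationConfig,
    simulate_methylome,
    simulate_population,
)


@pytest.fixture(scope="session")
def methylome_sim():
    """Full-size planted methylome: 1 Mb, 50 TEM + 50 GBM regions, 20x depth."""
    cfg = MethylomeConfig(seed=101)
    samples, truth = simulate_methylome(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def small_methylome_sim():
    """Quick methylome with TEM regions planted at gene features."""
    cfg = MethylomeConfig(
        seed=202,
        n_genes_per_chrom=40,
        n_tem=20,
        n_gbm=10,
        tem_promoter_frac=0.25,
        tem_tss_frac=0.25,
        tem_body_frac=0.25,
    )
    samples, truth = simulate_methylome(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def population_sim():
    cfg = PopulationConfig(seed=303)
    levels, truth = simulate_population(cfg)
    return cfg, levels, truth


def make_sample(rows, sample_id="s", genotype="other", condition="none"):
    """Build a MethylomeSample from (chrom, pos, strand, context, n_meth, n_total) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    return MethylomeSample(sample_id, genotype, condition, df)


def uniform_sample(
    chrom="chr1",
    start=0,
    end=1000,
    spacing=10,
    context="CG",
    level=0.5,
    depth=20,
    genotype="other",
):
    """Deterministic sample: evenly spaced sites, exact methylated fraction."""
    pos = np.arange(start, end, spacing)
    n_meth = int(round(level * depth))
    rows = [(chrom, int(p), "+", context, n_meth, depth) for p in pos]
    return make_sample(rows, genotype=genotype)
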