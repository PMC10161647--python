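"""Synthetic methylomes, expression matrices, and population panels.

Every generator emits data plus a ground-truth table, so pipeline output
can be scored against what was planted. The generative models are the
minimal ones consistent with the data types:

- methylomes: cytosine sites are placed with context-typical spacing
  (CG/CHG as symmetric strand pairs, CHH on one strand), read depth is
  Poisson, methylated counts are Binomial at the site's true level. True
  levels come from planted TEM-like regions (methylated in all three
  contexts), planted GBM regions (CG-only, inside gene bodies), and a low
  background. Genotype operators: a met1-like sample loses CG genome-wide,
  a ddcc-like sample loses CHG/CHH genome-wide, a ddm1-like sample drops
  all contexts at TEM-like regions and CG at the DDM1-dependent subset of
  GBM regions to a residual level.
- expression: log2 values = baseline + planted genotype/condition effects
  + Gaussian noise; hyper/sup genes carry a genotype x condition
  interaction confined to the BAsubDC condition.
- population: per-gene, per-accession gene-body levels; stable-GBM and
  stable-UM genes draw from tight Beta distributions, interchangeable
  genes flip state per accession with a gene-specific Bernoulli rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneModel, MethylomeSample, parse_sample_labels

# ---------------------------------------------------------------------------
# methylome simulation


@dataclass
class MethylomeConfig:
    seed: int = 0
    n_chroms: int = 1
    n_genes_per_chrom: int = 100
    slot_bp: int = 10_000  # one gene (and at most one planted element) per slot
    gene_length: int = 3000
    minus_strand_fraction: float = 0.5
    n_tem: int = 50
    n_gbm: int = 50
    tem_length: int = 1500
    gbm_length: int = 1600
    # feature placement of TEM regions (fractions; remainder is intergenic)
    tem_promoter_frac: float = 0.0
    tem_tss_frac: float = 0.0
    tem_body_frac: float = 0.0
    coverage: float = 20.0
    ddm1_dependent_fraction: float = 0.5
    # true levels (CG, CHG, CHH)
    tem_levels: tuple = (0.80, 0.40, 0.10)
    gbm_levels: tuple = (0.60, 0.01, 0.005)
    background_levels: tuple = (0.02, 0.005, 0.005)
    met1_cg: float = 0.01
    ddcc_noncg: float = 0.005
    ddm1_tem_residual: tuple = (0.05, 0.01, 0.01)
    ddm1_gbm_residual_cg: float = 0.05
    # mean site spacing (bp); CG/CHG symmetric pairs, CHH single-stranded
    spacing: dict = field(default_factory=lambda: {"CG": 15, "CHG": 20, "CHH": 8})
    conversion_failure: float = 0.0

    @property
    def chrom_length(self) -> int:
        return self.n_genes_per_chrom * self.slot_bp


@dataclass
class SyntheticTruth:
    """Planted ground truth: regions, gene models, and per-gene categories."""

    regions: pd.DataFrame  # chrom,start,end,klass,feature,gene_id,ddm1_dependent
    genes: list = field(default_factory=list)  # GeneModel
    gene_table: pd.DataFrame | None = None  # gene_id,...,true_category


def _plan_layout(cfg: MethylomeConfig, rng: np.random.Generator):
    """Deterministic slot layout: gene models plus planted-region intervals."""
    genes: list[GeneModel] = []
    region_rows = []
    n_slots = cfg.n_chroms * cfg.n_genes_per_chrom
    if cfg.n_tem + cfg.n_gbm > n_slots:
        raise ValueError("more planted elements than slots; enlarge the genome")
    # one planted element per slot: first n_gbm slots GBM, next n_tem slots TEM
    roles = ["gbm"] * cfg.n_gbm + ["tem"] * cfg.n_tem + ["none"] * (
        n_slots - cfg.n_gbm - cfg.n_tem
    )
    roles = list(rng.permutation(roles))
    n_feat_tem = {
        "promoter": int(round(cfg.tem_promoter_frac * cfg.n_tem)),
        "tss": int(round(cfg.tem_tss_frac * cfg.n_tem)),
        "body": int(round(cfg.tem_body_frac * cfg.n_tem)),
    }
    tem_features = (
        ["promoter"] * n_feat_tem["promoter"]
        + ["tss"] * n_feat_tem["tss"]
        + ["body"] * n_feat_tem["body"]
    )
    tem_features += ["intergenic"] * (cfg.n_tem - len(tem_features))
    tem_iter = iter(tem_features)
    ddm1_dep = rng.random(cfg.n_gbm) < cfg.ddm1_dependent_fraction
    gbm_i = 0
    slot_i = 0
    for chrom_i in range(cfg.n_chroms):
        chrom = f"chr{chrom_i + 1}"
        for local in range(cfg.n_genes_per_chrom):
            base = local * cfg.slot_bp
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            gene_id = f"G{slot_i + 1:04d}"
            g_start, g_end = base + 2000, base + 2000 + cfg.gene_length
            gene = GeneModel(gene_id, chrom, strand, g_start, g_end)
            genes.append(gene)
            role = roles[slot_i]
            slot_i += 1
            if role == "gbm":
                start = g_start + 300
                end = min(start + cfg.gbm_length, g_end - 400)
                region_rows.append(
                    (chrom, start, end, "GBM_LIKE", "body", gene_id, bool(ddm1_dep[gbm_i]))
                )
                gbm_i += 1
            elif role == "tem":
                feature = next(tem_iter)
                tss = gene.tss_point
                if feature == "promoter":
                    # strictly inside the promoter-only zone (no TSS overlap)
                    if strand == "+":
                        start, end = tss - 900, tss - 300
                    else:
                        start, end = tss + 300, tss + 900
                elif feature == "tss":
                    # the TSS-only zone: first 200 bp downstream of the TSS
                    start, end = (tss, tss + 200) if strand == "+" else (tss - 200, tss)
                elif feature == "body":
                    length = min(cfg.tem_length, cfg.gene_length - 800)
                    if strand == "+":
                        start = g_start + 400
                    else:
                        start = g_end - 400 - length
                    end = start + length
                else:  # intergenic, well clear of the gene and both promoters
                    start = base + 7000
                    end = start + min(cfg.tem_length, 1500)
                region_rows.append((chrom, start, end, "TEM_LIKE", feature, gene_id if feature != "intergenic" else "", False))
    regions = pd.DataFrame(
        region_rows,
        columns=["chrom", "start", "end", "klass", "feature", "gene_id", "ddm1_dependent"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    feature_to_cat = {"promoter": "pTEM", "tss": "tssTEM", "body": "gbTEM"}
    cat = {}
    for row in regions.itertuples(index=False):
        if row.klass == "GBM_LIKE":
            cat[row.gene_id] = "GBM"
        elif row.gene_id:
            cat[row.gene_id] = feature_to_cat.get(row.feature, "NONE")
    gene_table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "true_category": [cat.get(g.gene_id, "NONE") for g in genes],
        }
    )
    return SyntheticTruth(regions, genes, gene_table)


def _place_sites(cfg: MethylomeConfig, rng: np.random.Generator):
    """Cytosine positions per chromosome: dict chrom -> {context: (pos, strand)}."""
    out = {}
    for chrom_i in range(cfg.n_chroms):
        chrom = f"chr{chrom_i + 1}"
        per_ctx = {}
        for context, s in cfg.spacing.items():
            pair = context in ("CG", "CHG")  # symmetric contexts: both strands
            mean_step = s * (2 if pair else 1)
            n_approx = int(cfg.chrom_length / mean_step * 1.2) + 10
            steps = rng.integers(max(1, mean_step // 2), mean_step + mean_step // 2 + 1, n_approx)
            pos = np.cumsum(steps)
            pos = pos[pos < cfg.chrom_length - 1]
            if pair:
                all_pos = np.repeat(pos, 2)
                all_pos[1::2] += 1
                strand = np.tile(np.array(["+", "-"]), len(pos))
            else:
                all_pos = pos
                strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
            per_ctx[context] = (all_pos.astype(np.int64), strand)
        # a position/strand carries exactly one context: CG > CHG > CHH priority
        taken = np.empty(0, dtype=np.int64)
        for context in ("CG", "CHG", "CHH"):
            pos, strand = per_ctx[context]
            key = pos * 2 + (strand == "-")
            keep = ~np.isin(key, taken)
            per_ctx[context] = (pos[keep], strand[keep])
            taken = np.concatenate([taken, key[keep]])
        out[chrom] = per_ctx
    return out


_CTX_I = {"CG": 0, "CHG": 1, "CHH": 2}


def _true_levels(
    cfg: MethylomeConfig,
    truth: SyntheticTruth,
    chrom: str,
    context: str,
    pos: np.ndarray,
    genotype: str,
) -> np.ndarray:
    ci = _CTX_I[context]
    # genome-wide knockouts short-circuit the planted structure
    if genotype == "met1_like" and context == "CG":
        return np.full(pos.shape, cfg.met1_cg)
    if genotype == "ddcc_like" and context != "CG":
        return np.full(pos.shape, cfg.ddcc_noncg)
    level = np.full(pos.shape, cfg.background_levels[ci])
    sub = truth.regions[truth.regions["chrom"] == chrom]
    for row in sub.itertuples(index=False):
        lo, hi = np.searchsorted(pos, [row.start, row.end], side="left")
        if lo == hi:
            continue
        if row.klass == "TEM_LIKE":
            if genotype == "ddm1_like":
                level[lo:hi] = cfg.ddm1_tem_residual[ci]
            else:
                level[lo:hi] = cfg.tem_levels[ci]
        else:  # GBM_LIKE
            if genotype == "ddm1_like" and row.ddm1_dependent and context == "CG":
                level[lo:hi] = cfg.ddm1_gbm_residual_cg
            else:
                level[lo:hi] = cfg.gbm_levels[ci]
    return level


def simulate_methylome(
    cfg: MethylomeConfig | None = None,
    genotypes: tuple = ("wildtype", "met1_like", "ddcc_like", "ddm1_like"),
) -> tuple[dict, SyntheticTruth]:
    """Generate per-genotype methylome samples plus the planted truth.

    Returns ``(samples, truth)`` with ``samples[genotype]`` a
    :class:`~gbmscan.io.MethylomeSample`. Deterministic for a fixed
    ``cfg.seed``.
    """
    cfg = cfg or MethylomeConfig()
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(cfg.seed)
    truth = _plan_layout(cfg, rng)
    sites = _place_sites(cfg, rng)
    samples = {}
    for genotype in genotypes:
        frames = []
        for chrom in sorted(sites):
            for context in ("CG", "CHG", "CHH"):
                pos, strand = sites[chrom][context]
                level = _true_levels(cfg, truth, chrom, context, pos, genotype)
                if cfg.conversion_failure:
                    level = level + (1.0 - level) * cfg.conversion_failure
                n_total = rng.poisson(cfg.coverage, len(pos))
                n_meth = rng.binomial(n_total, level)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "strand": strand,
                            "context": context,
                            "n_meth": n_meth,
                            "n_total": n_total,
                        }
                    )
                )
        df = pd.concat(frames, ignore_index=True)
        samples[genotype] = MethylomeSample(f"sim_{genotype}", genotype, "none", df)
    return samples, truth


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class ExpressionConfig:
    seed: int = 0
    n_genes: int = 2200
    n_hyper: int = 100  # positive ddm1 x BAsubDC interaction
    n_sup: int = 100  # negative ddm1 x BAsubDC interaction
    n_basal_up: int = 0  # ddm1 main effect, all conditions
    n_basal_down: int = 0
    effect: float = 1.0  # log2 units
    baseline: float = 8.0
    noise_sd: float = 0.2
    n_replicates: int = 3
    genotypes: tuple = ("wildtype", "ddm1_like")
    conditions: tuple = ("mock", "BAsub", "mockDC", "BAsubDC")
    interaction_condition: str = "BAsubDC"


def simulate_expression(cfg: ExpressionConfig | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a labeled log2 expression matrix plus per-gene truth roles.

    Roles: ``hyper`` (+effect in the mutant under the interaction
    condition), ``sup`` (-effect there), ``basal_up``/``basal_down``
    (mutant main effect under every condition), ``null``.
    """
    cfg = cfg or ExpressionConfig()
    n_planted = cfg.n_hyper + cfg.n_sup + cfg.n_basal_up + cfg.n_basal_down
    if n_planted > cfg.n_genes:
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(cfg.seed)
    roles = np.array(
        ["hyper"] * cfg.n_hyper
        + ["sup"] * cfg.n_sup
        + ["basal_up"] * cfg.n_basal_up
        + ["basal_down"] * cfg.n_basal_down
        + ["null"] * (cfg.n_genes - n_planted)
    )
    rng.shuffle(roles)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    columns = []
    effects = []
    for genotype in cfg.genotypes:
        for condition in cfg.conditions:
            for rep in range(1, cfg.n_replicates + 1):
                columns.append(f"{genotype}.{condition}.{rep}")
                eff = np.zeros(cfg.n_genes)
                if genotype != "wildtype":
                    if condition == cfg.interaction_condition:
                        eff[roles == "hyper"] += cfg.effect
                        eff[roles == "sup"] -= cfg.effect
                    eff[roles == "basal_up"] += cfg.effect
                    eff[roles == "basal_down"] -= cfg.effect
                effects.append(eff)
    mean = cfg.baseline + np.column_stack(effects)
    values = mean + rng.normal(0.0, cfg.noise_sd, mean.shape)
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns)
    truth = pd.DataFrame({"gene_id": gene_ids, "role": roles}).set_index("gene_id")
    return ExpressionMatrix(df, parse_sample_labels(df.columns)), truth


# ---------------------------------------------------------------------------
# population simulation


@dataclass
class PopulationConfig:
    seed: int = 0
    n_genes: int = 2000
    n_accessions: int = 927
    # planted class proportions (remainder: intermediate-methylation genes)
    frac_stable_gbm: float = 0.26
    frac_stable_um: float = 0.42
    frac_interchangeable: float = 0.17
    gbm_mean: float = 0.30
    gbm_conc: float = 50.0
    um_mean: float = 0.01
    um_conc: float = 50.0
    intermediate_mean: float = 0.075
    intermediate_conc: float = 200.0
    theta_range: tuple = (0.15, 0.70)  # per-gene GBM rate of interchangeable genes
    noncg_mean: float = 0.005
    noncg_conc: float = 200.0


def _beta(rng, mean, conc, size):
    return rng.beta(mean * conc, (1.0 - mean) * conc, size)


def simulate_population(cfg: PopulationConfig | None = None):
    """Per-accession gene-body methylation with planted stability classes.

    Returns ``(levels, truth)``: ``levels`` is a dict with 'mCG', 'mCHG',
    'mCHH' genes x accessions frames, ``truth`` maps gene_id to the
    planted class (GBM_NV / UM_NV / IM_NV / OTHER).
    """
    cfg = cfg or PopulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_gbm = int(round(cfg.frac_stable_gbm * cfg.n_genes))
    n_um = int(round(cfg.frac_stable_um * cfg.n_genes))
    n_im = int(round(cfg.frac_interchangeable * cfg.n_genes))
    n_other = cfg.n_genes - n_gbm - n_um - n_im
    if n_other < 0:
        raise ValueError("class fractions exceed 1")
    classes = np.array(
        ["GBM_NV"] * n_gbm + ["UM_NV"] * n_um + ["IM_NV"] * n_im + ["OTHER"] * n_other
    )
    rng.shuffle(classes)
    shape = (cfg.n_genes, cfg.n_accessions)
    mcg = np.empty(shape)
    mask = classes == "GBM_NV"
    mcg[mask] = _beta(rng, cfg.gbm_mean, cfg.gbm_conc, (int(mask.sum()), cfg.n_accessions))
    mask = classes == "UM_NV"
    mcg[mask] = _beta(rng, cfg.um_mean, cfg.um_conc, (int(mask.sum()), cfg.n_accessions))
    mask = classes == "OTHER"
    mcg[mask] = _beta(
        rng, cfg.intermediate_mean, cfg.intermediate_conc, (int(mask.sum()), cfg.n_accessions)
    )
    mask = classes == "IM_NV"
    n_im_actual = int(mask.sum())
    theta = rng.uniform(*cfg.theta_range, n_im_actual)
    is_gbm = rng.random((n_im_actual, cfg.n_accessions)) < theta[:, None]
    im_levels = np.where(
        is_gbm,
        _beta(rng, cfg.gbm_mean, cfg.gbm_conc, (n_im_actual, cfg.n_accessions)),
        _beta(rng, cfg.um_mean, cfg.um_conc, (n_im_actual, cfg.n_accessions)),
    )
    mcg[mask] = im_levels
    mchg = _beta(rng, cfg.noncg_mean, cfg.noncg_conc, shape)
    mchh = _beta(rng, cfg.noncg_mean, cfg.noncg_conc, shape)
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(cfg.n_genes)], name="gene_id")
    acc = [f"acc{i + 1:04d}" for i in range(cfg.n_accessions)]
    levels = {
        "mCG": pd.DataFrame(mcg, index=gene_ids, columns=acc),
        "mCHG": pd.DataFrame(mchg, index=gene_ids, columns=acc),
        "mCHH": pd.DataFrame(mchh, index=gene_ids, columns=acc),
    }
    truth = pd.DataFrame({"gene_id": gene_ids, "true_class": classes}).set_index("gene_id")
    return levels, truth
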