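"""Differential hypomethylation calls between genotypes.

A classified region (or the pooled counts of all regions on a gene) is
called STRONGLY_DEMETHYLATED in a mutant when, for every context the mode
requires, the methylation loss (mutant - reference) clears a negative
delta threshold, a one-sided Fisher exact test on the pooled counts is
significant, and the residual mutant level is below a cap. Modes:

- ``gbm``: CG only (loss <= -0.1, p <= 0.001, residual mCG <= 0.15) —
  separates GBM-like regions into a strongly demethylated (ddm1-dependent)
  and a weak group;
- ``tem``: all three contexts jointly (CG loss <= -0.1, CHG <= -0.05,
  CHH <= -0.02; residuals mCG <= 0.15, mCHG <= 0.1, mCHH <= 0.05);
- ``drm2_chh``: CHH only (loss <= -0.02, residual mCHH <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GeneModel, GenomicInterval, MethylomeSample
from .regions import ClassifiedRegion, RegionLevelIndex
from .stats import fisher_exact

MODES = ("gbm", "tem", "drm2_chh")

STRONG = "STRONGLY_DEMETHYLATED"
WEAK = "WEAK"


@dataclass
class ContextCriteria:
    max_delta: float  # loss threshold, negative (mutant - reference)
    max_p: float
    max_residual: float  # cap on the mutant's remaining level


@dataclass
class DiffThresholds:
    """Per-mode criteria; defaults are the published cutoffs."""

    gbm: dict = field(
        default_factory=lambda: {"CG": ContextCriteria(-0.1, 1e-3, 0.15)}
    )
    tem: dict = field(
        default_factory=lambda: {
            "CG": ContextCriteria(-0.1, 1e-3, 0.15),
            "CHG": ContextCriteria(-0.05, 1e-3, 0.10),
            "CHH": ContextCriteria(-0.02, 1e-3, 0.05),
        }
    )
    drm2_chh: dict = field(
        default_factory=lambda: {"CHH": ContextCriteria(-0.02, 1e-3, 0.05)}
    )

    def for_mode(self, mode: str) -> dict:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        return getattr(self, mode)


@dataclass
class DiffMethCall:
    target: str
    mode: str
    status: str  # STRONGLY_DEMETHYLATED | WEAK
    delta: dict = field(default_factory=dict)  # context -> mutant - reference level
    p: dict = field(default_factory=dict)  # context -> one-sided Fisher p (loss)
    mut_level: dict = field(default_factory=dict)
    ref_level: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _call_from_counts(
    target: str,
    mode: str,
    ref_counts: dict,
    mut_counts: dict,
    thr: DiffThresholds,
) -> DiffMethCall:
    criteria = thr.for_mode(mode)
    call = DiffMethCall(target, mode, STRONG)
    for context, crit in criteria.items():
        rm, rt = ref_counts.get(context, (0, 0))
        mm, mt = mut_counts.get(context, (0, 0))
        if rt == 0 or mt == 0:
            # no coverage for a required context: conservative WEAK
            call.status = WEAK
            call.flags.append(f"no_coverage_{context}")
            continue
        ref_level = rm / rt
        mut_level = mm / mt
        delta = mut_level - ref_level
        # one-sided test: reference more methylated than the mutant
        p = fisher_exact([[rm, rt - rm], [mm, mt - mm]], "greater")
        call.delta[context] = delta
        call.p[context] = p
        call.ref_level[context] = ref_level
        call.mut_level[context] = mut_level
        if not (delta <= crit.max_delta and p <= crit.max_p and mut_level <= crit.max_residual):
            call.status = WEAK
    return call


def _pooled(index: RegionLevelIndex, intervals: Sequence[GenomicInterval], contexts) -> dict:
    counts = {}
    for context in contexts:
        m = t = 0
        for iv in intervals:
            dm, dt = index.pooled_counts(iv, context)
            m += dm
            t += dt
        counts[context] = (m, t)
    return counts


def diff_region(
    region: ClassifiedRegion,
    ref: MethylomeSample,
    mut: MethylomeSample,
    mode: str = "gbm",
    thr: DiffThresholds | None = None,
) -> DiffMethCall:
    """Hypomethylation status of one classified region (mutant vs reference)."""
    thr = thr or DiffThresholds()
    contexts = list(thr.for_mode(mode))
    iv = region.interval
    target = region.interval.label or f"{iv.chrom}:{iv.start}-{iv.end}"
    ref_counts = _pooled(RegionLevelIndex(ref), [iv], contexts)
    mut_counts = _pooled(RegionLevelIndex(mut), [iv], contexts)
    return _call_from_counts(target, mode, ref_counts, mut_counts, thr)


def diff_regions(
    regions: Sequence[ClassifiedRegion],
    ref: MethylomeSample,
    mut: MethylomeSample,
    mode: str = "gbm",
    thr: DiffThresholds | None = None,
) -> list[DiffMethCall]:
    """Vector form of :func:`diff_region` (indexes each sample once)."""
    thr = thr or DiffThresholds()
    contexts = list(thr.for_mode(mode))
    ref_idx, mut_idx = RegionLevelIndex(ref), RegionLevelIndex(mut)
    calls = []
    for i, region in enumerate(regions):
        iv = region.interval
        target = iv.label or f"{iv.chrom}:{iv.start}-{iv.end}"
        calls.append(
            _call_from_counts(
                target,
                mode,
                _pooled(ref_idx, [iv], contexts),
                _pooled(mut_idx, [iv], contexts),
                thr,
            )
        )
    return calls


def diff_gene(
    gene: GeneModel,
    regions: Iterable[ClassifiedRegion],
    ref: MethylomeSample,
    mut: MethylomeSample,
    mode: str = "gbm",
    thr: DiffThresholds | None = None,
) -> DiffMethCall:
    """Gene-level call: counts of all the gene's regions pooled per context.

    Methylated and unmethylated read counts are summed across the regions
    assigned to the gene, then the same delta / p / residual criteria are
    applied to the pooled table.
    """
    thr = thr or DiffThresholds()
    contexts = list(thr.for_mode(mode))
    intervals = [r.interval for r in regions]
    if not intervals:
        raise ValueError(f"{gene.gene_id}: no regions to pool")
    ref_counts = _pooled(RegionLevelIndex(ref), intervals, contexts)
    mut_counts = _pooled(RegionLevelIndex(mut), intervals, contexts)
    return _call_from_counts(gene.gene_id, mode, ref_counts, mut_counts, thr)


def diff_genes(
    gene_regions: dict,
    genes: Sequence[GeneModel],
    ref: MethylomeSample,
    mut: MethylomeSample,
    mode: str = "gbm",
    thr: DiffThresholds | None = None,
) -> list[DiffMethCall]:
    """Gene-level calls for many genes; ``gene_regions`` maps gene_id -> regions."""
    thr = thr or DiffThresholds()
    contexts = list(thr.for_mode(mode))
    ref_idx, mut_idx = RegionLevelIndex(ref), RegionLevelIndex(mut)
    calls = []
    for gene in genes:
        regions = gene_regions.get(gene.gene_id, [])
        if not regions:
            continue
        intervals = [r.interval for r in regions]
        calls.append(
            _call_from_counts(
                gene.gene_id,
                mode,
                _pooled(ref_idx, intervals, contexts),
                _pooled(mut_idx, intervals, contexts),
                thr,
            )
        )
    return calls
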