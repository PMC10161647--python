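"""Assignment of methylated regions to gene features and gene categorization.

Each gene defines three strand-aware feature zones from configurable
widths: promoter (default 1 kb upstream of the TSS), TSS window (TSS
+/- 200 bp), and gene body (gene span minus the TSS window). Note the
promoter and the TSS window deliberately overlap on the 200 bp just
upstream of the TSS: a region confined there hits both features, and a
gene whose regions hit more than one feature is excluded as ambiguous.

Categorization is mutually exclusive: a gene with regions of one class in
exactly one feature gets pTEM/tssTEM/gbTEM (or pGBM/tssGBM/GBM for the
GBM-like class, where a body region that also touches the TSS window is
reassigned to tssGBM); same-class regions in several features give
EXCLUDED_MULTI; both classes on one gene give EXCLUDED_MIXED; genes with
no region give NONE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GeneModel, GenomicInterval
from .regions import ClassifiedRegion

CATEGORIES = (
    "pTEM",
    "tssTEM",
    "gbTEM",
    "pGBM",
    "tssGBM",
    "GBM",
    "EXCLUDED_MULTI",
    "EXCLUDED_MIXED",
    "NONE",
)

_TEM_BY_FEATURE = {"promoter": "pTEM", "tss": "tssTEM", "body": "gbTEM"}
_GBM_BY_FEATURE = {"promoter": "pGBM", "tss": "tssGBM", "body": "GBM"}


@dataclass
class FeatureConfig:
    """Widths of the derived gene features, in bp."""

    promoter_bp: int = 1000
    tss_flank: int = 200


@dataclass
class GeneContextCall:
    gene_id: str
    category: str
    region_ids: list = field(default_factory=list)


def assign_feature(
    region: ClassifiedRegion | GenomicInterval,
    gene: GeneModel,
    config: FeatureConfig | None = None,
) -> set[str]:
    """Feature memberships of a region on one gene, by >=1 bp overlap."""
    cfg = config or FeatureConfig()
    iv = region.interval if isinstance(region, ClassifiedRegion) else region
    features: set[str] = set()
    promoter = gene.promoter_interval(cfg.promoter_bp)
    if promoter is not None and iv.overlaps(promoter):
        features.add("promoter")
    if iv.overlaps(gene.tss_interval(cfg.tss_flank)):
        features.add("tss")
    body = gene.body_interval(cfg.tss_flank)
    if body is not None and iv.overlaps(body):
        features.add("body")
    return features


def categorize_genes(
    regions: Sequence[ClassifiedRegion],
    genes: Iterable[GeneModel],
    config: FeatureConfig | None = None,
) -> list[GeneContextCall]:
    """Mutually exclusive methylation-location category for every gene.

    A region overlapping several genes contributes to each independently
    (regions are unstranded; no strand filter is applied).
    """
    cfg = config or FeatureConfig()
    calls = []
    for gene in genes:
        klasses: set[str] = set()
        features: set[str] = set()
        hits: list[str] = []
        tss_iv = gene.tss_interval(cfg.tss_flank)
        gbm_body_touches_tss = False
        for ridx, region in enumerate(regions):
            feats = assign_feature(region, gene, cfg)
            if not feats:
                continue
            klasses.add(region.klass)
            features |= feats
            iv = region.interval
            hits.append(iv.label or f"{iv.chrom}:{iv.start}-{iv.end}")
            if region.klass == "GBM_LIKE" and "body" in feats and iv.overlaps(tss_iv):
                gbm_body_touches_tss = True
        if not hits:
            calls.append(GeneContextCall(gene.gene_id, "NONE"))
            continue
        if len(klasses) > 1:
            calls.append(GeneContextCall(gene.gene_id, "EXCLUDED_MIXED", hits))
            continue
        klass = klasses.pop()
        if klass == "GBM_LIKE" and features == {"tss", "body"} and gbm_body_touches_tss:
            # GBM-like in the body but overlapping the TSS window: tssGBM
            calls.append(GeneContextCall(gene.gene_id, "tssGBM", hits))
            continue
        if len(features) > 1:
            calls.append(GeneContextCall(gene.gene_id, "EXCLUDED_MULTI", hits))
            continue
        feature = features.pop()
        table = _TEM_BY_FEATURE if klass == "TEM_LIKE" else _GBM_BY_FEATURE
        calls.append(GeneContextCall(gene.gene_id, table[feature], hits))
    return calls


def regions_by_gene(
    regions: Sequence[ClassifiedRegion],
    genes: Iterable[GeneModel],
    config: FeatureConfig | None = None,
) -> dict[str, list[ClassifiedRegion]]:
    """Map gene_id -> regions overlapping any of the gene's feature zones."""
    cfg = config or FeatureConfig()
    out: dict[str, list[ClassifiedRegion]] = {}
    for gene in genes:
        assigned = [r for r in regions if assign_feature(r, gene, cfg)]
        if assigned:
            out[gene.gene_id] = assigned
    return out
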