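"""Gene-set overlap enrichment, term enrichment, metaprofiles, clustering.

- overlap_enrichment: observed-to-expected ratio of the overlap of two
  gene sets within a universe, with a one-sided Fisher exact p-value
  (over-representation).
- term_enrichment: hypergeometric enrichment of a query set against a
  user-supplied term -> genes annotation, filtered at FDR <= 0.01 and
  fold enrichment >= 2.
- metaprofile: pooled methylation level in length-scaled gene-body bins
  plus fixed-width flanks, strand-oriented.
- cluster_features: 2-cluster Ward hierarchical clustering of a centered,
  unit-variance gene x chromatin-feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .io import GeneModel, MethylomeSample
from .stats import bh_fdr, fisher_exact


@dataclass
class EnrichmentResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    observed_overlap: int
    expected: float
    ratio: float
    p: float


def overlap_enrichment(a: Iterable, b: Iterable, universe: Iterable) -> EnrichmentResult:
    """Observed:expected overlap of two gene sets within a universe."""
    uni = set(universe)
    sa = set(a) & uni
    sb = set(b) & uni
    if set(a) - uni or set(b) - uni:
        raise ValueError("gene sets must be subsets of the universe")
    observed = len(sa & sb)
    expected = len(sa) * len(sb) / len(uni) if uni else 0.0
    ratio = observed / expected if expected > 0 else 0.0
    table = [
        [observed, len(sa) - observed],
        [len(sb) - observed, len(uni) - len(sa) - len(sb) + observed],
    ]
    return EnrichmentResult(
        len(sa), len(sb), len(uni), observed, expected, ratio, fisher_exact(table, "greater")
    )


def term_enrichment(
    query: Iterable,
    annotation: Mapping[str, Iterable],
    universe: Iterable,
    fdr_max: float = 0.01,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Significantly enriched terms for a query gene set.

    fold = (overlap/|query|) / (|term in universe|/|universe|); p is the
    hypergeometric upper tail; q is Benjamini-Hochberg across all terms.
    Only terms with q <= fdr_max and fold >= fold_min are returned.
    """
    uni = set(universe)
    q = set(query) & uni
    if not q:
        raise ValueError("query set is empty within the universe")
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & uni
        if not term_genes:
            continue
        overlap = len(q & term_genes)
        fold = (overlap / len(q)) / (len(term_genes) / len(uni))
        p = float(sps.hypergeom.sf(overlap - 1, len(uni), len(term_genes), len(q)))
        rows.append((term, len(term_genes), overlap, fold, p))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "fold", "p"])
    if len(df) == 0:
        df["q"] = []
        return df
    df["q"] = bh_fdr(df["p"].to_numpy())
    keep = (df["q"] <= fdr_max) & (df["fold"] >= fold_min)
    return df.loc[keep].sort_values(["q", "p", "term"]).reset_index(drop=True)


def metaprofile(
    samples: MethylomeSample | Sequence[MethylomeSample],
    genes: Sequence[GeneModel],
    context: str,
    flank_bp: int = 1000,
    n_flank_bins: int = 20,
    n_body_bins: int = 40,
) -> pd.DataFrame:
    """Average methylation around genes: fixed flank bins, scaled body bins.

    Bins run 5'->3' in gene orientation (minus-strand genes are flipped):
    ``n_flank_bins`` upstream, ``n_body_bins`` across the body (positions
    scaled by gene length), ``n_flank_bins`` downstream. Bin level is the
    pooled sum(n_meth)/sum(n_total) over all genes and samples; columns:
    bin, zone, level, n_meth, n_total.
    """
    if isinstance(samples, MethylomeSample):
        samples = [samples]
    n_bins = 2 * n_flank_bins + n_body_bins
    meth = np.zeros(n_bins, dtype=np.int64)
    total = np.zeros(n_bins, dtype=np.int64)
    for sample in samples:
        df = sample.cytosines
        df = df[df["context"] == context]
        by_chrom = dict(tuple(df.groupby("chrom", sort=False)))
        for gene in genes:
            sub = by_chrom.get(gene.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            lo, hi = gene.start - flank_bp, gene.end + flank_bp
            i0, i1 = np.searchsorted(pos, [lo, hi], side="left")
            if i0 == i1:
                continue
            p = pos[i0:i1]
            m = sub["n_meth"].to_numpy()[i0:i1]
            t = sub["n_total"].to_numpy()[i0:i1]
            length = gene.end - gene.start
            upstream = p < gene.start
            body = (p >= gene.start) & (p < gene.end)
            down = p >= gene.end
            bins = np.empty(p.shape, dtype=np.int64)
            bins[upstream] = (p[upstream] - lo) * n_flank_bins // flank_bp
            bins[body] = n_flank_bins + (p[body] - gene.start) * n_body_bins // length
            bins[down] = (
                n_flank_bins + n_body_bins + (p[down] - gene.end) * n_flank_bins // flank_bp
            )
            if gene.strand == "-":
                bins = n_bins - 1 - bins
            np.add.at(meth, bins, m)
            np.add.at(total, bins, t)
    zone = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    with np.errstate(invalid="ignore"):
        level = np.where(total > 0, meth / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "zone": zone, "level": level, "n_meth": meth, "n_total": total}
    )


def cluster_features(matrix: pd.DataFrame, k: int = 2) -> pd.Series:
    """Hierarchical 2-way clustering of a genes x features matrix.

    Features are centered and scaled to unit variance (constant features
    become zero), distances are Euclidean, linkage is Ward, and the tree is
    cut at ``k``. Labels are renumbered 1..k by order of each cluster's
    first member in sorted row-label order, so the assignment is invariant
    to row order. A degenerate matrix (all rows identical) yields one
    effective cluster (all labels 1).
    """
    if matrix.isna().any().any():
        raise ValueError("feature matrix must be complete")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    order = np.argsort(matrix.index.to_numpy())
    if np.allclose(x, x[0]):
        return pd.Series(1, index=matrix.index, name="cluster")
    z = linkage(x[order], method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber by first appearance along the sorted row labels
    relabel: dict[int, int] = {}
    for lbl in raw:
        if lbl not in relabel:
            relabel[lbl] = len(relabel) + 1
    labels = np.empty(len(raw), dtype=np.int64)
    labels[order] = [relabel[lbl] for lbl in raw]
    return pd.Series(labels, index=matrix.index, name="cluster")
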