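"""Windowed Fisher-exact region calling and TEM/GBM classification.

The genome is tiled with fixed, genome-anchored 50-bp windows. For each
context a window's pooled counts in the wild-type sample are tested
against a demethylated baseline (CG vs a met1-like sample; CHG/CHH vs a
ddcc-like sample) with a one-sided Fisher exact test. Significant windows
of one context are merged when closer than 500 bp; merged CG regions are
then split into transposon-like (TEM-like: overlapping merged nonCG
regions, methylated in all three contexts) and gene-body-like (GBM-like:
CG-only) classes by average methylation level thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS, GenomicInterval, MethylomeSample
from .stats import fisher_greater_vec

WINDOW_SIZE = 50

#: baseline genotype expected per context ("vs. met1" for CG, "vs. ddcc" for nonCG)
BASELINE_GENOTYPE = {"CG": "met1_like", "CHG": "ddcc_like", "CHH": "ddcc_like"}


@dataclass
class ClassThresholds:
    """Cutoffs for window significance and region classification."""

    p_cg: float = 1e-14
    p_chg: float = 1e-4
    p_chh: float = 1e-8
    merge_gap: int = 500
    tem_cg_min: float = 0.10
    tem_chg_min: float = 0.05
    tem_chh_min: float = 0.02
    gbm_cg_min: float = 0.10
    gbm_chg_max: float = 0.05
    gbm_chh_max: float = 0.02
    min_sites: int = 2  # covered cytosines of the tested context per window

    def p_cutoff(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}[context]


@dataclass
class ClassifiedRegion:
    """A merged region labeled TEM-like or GBM-like with pooled levels."""

    interval: GenomicInterval
    klass: str  # TEM_LIKE | GBM_LIKE
    mean_mcg: float
    mean_mchg: float
    mean_mchh: float
    counts: dict = field(default_factory=dict)  # context -> (n_meth, n_total)


def _window_counts(sample: MethylomeSample, context: str, window: int) -> pd.DataFrame:
    sub = sample.cytosines
    sub = sub[(sub["context"] == context) & (sub["n_total"] > 0)]
    if len(sub) == 0:
        return pd.DataFrame(columns=["chrom", "widx", "n_meth", "n_total", "n_sites"])
    widx = sub["pos"].to_numpy() // window
    grouped = (
        pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "widx": widx,
                "n_meth": sub["n_meth"].to_numpy(),
                "n_total": sub["n_total"].to_numpy(),
            }
        )
        .groupby(["chrom", "widx"], sort=True)
        .agg(n_meth=("n_meth", "sum"), n_total=("n_total", "sum"), n_sites=("n_total", "size"))
        .reset_index()
    )
    return grouped


def call_significant_windows(
    sample: MethylomeSample,
    baseline: MethylomeSample,
    context: str,
    p_cutoff: float | None = None,
    thresholds: ClassThresholds | None = None,
    window: int = WINDOW_SIZE,
    enforce_baseline: bool = True,
) -> pd.DataFrame:
    """Return significant 50-bp windows for one context.

    Output columns: chrom, start, end, n_meth, n_total, n_sites,
    baseline_meth, baseline_total, p. Windows need at least
    ``thresholds.min_sites`` covered cytosines and a one-sided Fisher
    p <= cutoff (sample more methylated than the baseline).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    thr = thresholds or ClassThresholds()
    if p_cutoff is None:
        p_cutoff = thr.p_cutoff(context)
    if enforce_baseline and baseline.genotype != BASELINE_GENOTYPE[context]:
        raise ValueError(
            f"{context} windows must be tested against a "
            f"{BASELINE_GENOTYPE[context]} baseline, got {baseline.genotype!r}"
        )
    ws = _window_counts(sample, context, window)
    wb = _window_counts(baseline, context, window)
    merged = ws.merge(wb, on=["chrom", "widx"], how="left", suffixes=("", "_b"))
    merged[["n_meth_b", "n_total_b"]] = (
        merged[["n_meth_b", "n_total_b"]].fillna(0).astype(np.int64)
    )
    a = merged["n_meth"].to_numpy()
    b = merged["n_total"].to_numpy() - a
    c = merged["n_meth_b"].to_numpy()
    d = merged["n_total_b"].to_numpy() - c
    p = fisher_greater_vec(a, b, c, d)
    keep = (p <= p_cutoff) & (merged["n_sites"].to_numpy() >= thr.min_sites)
    out = merged.loc[keep].copy()
    out["start"] = out["widx"] * window
    out["end"] = out["start"] + window
    out["p"] = p[keep]
    out = out.rename(columns={"n_meth_b": "baseline_meth", "n_total_b": "baseline_total"})
    cols = ["chrom", "start", "end", "n_meth", "n_total", "n_sites", "baseline_meth", "baseline_total", "p"]
    return out[cols].sort_values(["chrom", "start"]).reset_index(drop=True)


def _to_intervals(windows) -> list[GenomicInterval]:
    if isinstance(windows, pd.DataFrame):
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in windows.itertuples(index=False)
        ]
    return list(windows)


def merge_windows(windows, merge_gap: int = 500) -> list[GenomicInterval]:
    """Merge same-context intervals whose gap is strictly below ``merge_gap``.

    The gap between two intervals is next.start - prev.end; overlapping or
    touching intervals always merge. The result is sorted, disjoint, and
    independent of input order.
    """
    ivs = sorted(_to_intervals(windows), key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end < merge_gap:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def union_intervals(*interval_lists) -> list[GenomicInterval]:
    """Union of interval sets: overlapping or touching intervals coalesce."""
    all_ivs: list[GenomicInterval] = []
    for lst in interval_lists:
        all_ivs.extend(_to_intervals(lst))
    return merge_windows(all_ivs, merge_gap=1)


class _OverlapIndex:
    """Overlap queries against a sorted, disjoint interval set."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            self._by_chrom[chrom] = (
                np.array([iv.start for iv in ivs]),
                np.array([iv.end for iv in ivs]),
            )

    def overlaps(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[iv.chrom]
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and ends[i - 1] > iv.start


def region_level(
    sample: MethylomeSample, interval: GenomicInterval, context: str
) -> tuple[float, int, int]:
    """Pooled methylation level over one interval: (level, n_meth, n_total).

    The level is sum(n_meth)/sum(n_total) over covered cytosines of the
    context inside the interval; with zero coverage it is reported as 0.0
    with n_total = 0 (callers treat that as undefined).
    """
    df = sample.cytosines
    sub = df[
        (df["context"] == context)
        & (df["chrom"] == interval.chrom)
        & (df["pos"] >= interval.start)
        & (df["pos"] < interval.end)
    ]
    n_meth = int(sub["n_meth"].sum())
    n_total = int(sub["n_total"].sum())
    level = n_meth / n_total if n_total else 0.0
    return level, n_meth, n_total


class RegionLevelIndex:
    """Fast pooled-count queries for many intervals against one sample.

    Builds per-(chrom, context) cumulative count arrays once; each query is
    two binary searches.
    """

    def __init__(self, sample: MethylomeSample):
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        df = sample.cytosines
        for (chrom, context), sub in df.groupby(["chrom", "context"], sort=False):
            pos = sub["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())])
            ct = np.concatenate([[0], np.cumsum(sub["n_total"].to_numpy())])
            self._idx[(chrom, context)] = (pos, cm, ct)

    def pooled_counts(self, interval: GenomicInterval, context: str) -> tuple[int, int]:
        key = (interval.chrom, context)
        if key not in self._idx:
            return 0, 0
        pos, cm, ct = self._idx[key]
        lo = int(np.searchsorted(pos, interval.start, side="left"))
        hi = int(np.searchsorted(pos, interval.end, side="left"))
        return int(cm[hi] - cm[lo]), int(ct[hi] - ct[lo])

    def level(self, interval: GenomicInterval, context: str) -> tuple[float, int, int]:
        m, t = self.pooled_counts(interval, context)
        return (m / t if t else 0.0), m, t


def classify_regions(
    cg_regions: Iterable[GenomicInterval],
    chg_regions: Iterable[GenomicInterval],
    chh_regions: Iterable[GenomicInterval],
    sample: MethylomeSample,
    thresholds: ClassThresholds | None = None,
) -> list[ClassifiedRegion]:
    """Split merged CG regions into TEM-like and GBM-like classes.

    A CG region overlapping the union of merged CHG and CHH regions is a
    TEM-like candidate; one with no nonCG overlap is a GBM-like candidate.
    Candidates must additionally pass the average-level thresholds (TEM:
    CG>=0.1, CHG>=0.05, CHH>=0.02; GBM: CG>=0.1, CHG<=0.05, CHH<=0.02),
    computed from pooled counts over the region; the rest are dropped.
    """
    thr = thresholds or ClassThresholds()
    noncg = _OverlapIndex(union_intervals(chg_regions, chh_regions))
    levels = RegionLevelIndex(sample)
    out: list[ClassifiedRegion] = []
    for iv in _to_intervals(cg_regions):
        mcg, m_cg, t_cg = levels.level(iv, "CG")
        mchg, m_chg, t_chg = levels.level(iv, "CHG")
        mchh, m_chh, t_chh = levels.level(iv, "CHH")
        counts = {"CG": (m_cg, t_cg), "CHG": (m_chg, t_chg), "CHH": (m_chh, t_chh)}
        if noncg.overlaps(iv):
            if mcg >= thr.tem_cg_min and mchg >= thr.tem_chg_min and mchh >= thr.tem_chh_min:
                out.append(ClassifiedRegion(iv, "TEM_LIKE", mcg, mchg, mchh, counts))
        else:
            if mcg >= thr.gbm_cg_min and mchg <= thr.gbm_chg_max and mchh <= thr.gbm_chh_max:
                out.append(ClassifiedRegion(iv, "GBM_LIKE", mcg, mchg, mchh, counts))
    return out


def read_regions_bed(path) -> list[ClassifiedRegion]:
    """Read classified regions written by :func:`gbmscan.io.write_regions_bed`."""
    out: list[ClassifiedRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 BED columns")
            chrom, start, end, klass, mcg, mchg, mchh = parts[:7]
            out.append(
                ClassifiedRegion(
                    GenomicInterval(chrom, int(start), int(end)),
                    klass,
                    float(mcg),
                    float(mchg),
                    float(mchh),
                )
            )
    return out


def call_regions(
    sample: MethylomeSample,
    met1_baseline: MethylomeSample,
    ddcc_baseline: MethylomeSample,
    thresholds: ClassThresholds | None = None,
    enforce_baseline: bool = True,
) -> list[ClassifiedRegion]:
    """End-to-end region calling: windows -> merge per context -> classify."""
    thr = thresholds or ClassThresholds()
    merged = {}
    for context, baseline in (("CG", met1_baseline), ("CHG", ddcc_baseline), ("CHH", ddcc_baseline)):
        wins = call_significant_windows(
            sample, baseline, context, thresholds=thr, enforce_baseline=enforce_baseline
        )
        merged[context] = merge_windows(wins, thr.merge_gap)
    return classify_regions(merged["CG"], merged["CHG"], merged["CHH"], sample, thr)
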