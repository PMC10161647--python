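"""Population-scale gene-body-methylation state and stability classes.

Each gene x accession carries mean gene-body methylation levels in the
three contexts. Per accession a gene is UM (unmethylated body: CG <= 0.05,
CHG <= 0.05, CHH <= 0.02), GBM (CG >= 0.1, CHG <= 0.05, CHH <= 0.02), or
UNCLASSIFIED (intermediate CG or elevated nonCG; missing values too).
Across the panel a gene is GBM_NV (GBM in more than ``gbm_nv_min``
accessions, default 700 of 927), UM_NV (UM in more than 700), IM_NV
(GBM in 100-700, inclusive; interchangeable), or OTHER. The stable
classes take precedence over IM_NV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UM = "UM"
GBM = "GBM"
UNCLASSIFIED = "UNCLASSIFIED"

CLASSES = ("GBM_NV", "IM_NV", "UM_NV", "OTHER")


@dataclass
class StateThresholds:
    um_cg_max: float = 0.05
    gbm_cg_min: float = 0.10
    chg_max: float = 0.05
    chh_max: float = 0.02


def classify_state(
    mcg: float, mchg: float, mchh: float, thr: StateThresholds | None = None
) -> str:
    """Methylation state of one gene body in one accession."""
    thr = thr or StateThresholds()
    if any(pd.isna(v) for v in (mcg, mchg, mchh)):
        return UNCLASSIFIED
    if mchg > thr.chg_max or mchh > thr.chh_max:
        return UNCLASSIFIED
    if mcg <= thr.um_cg_max:
        return UM
    if mcg >= thr.gbm_cg_min:
        return GBM
    return UNCLASSIFIED


def state_matrix(
    mcg: pd.DataFrame,
    mchg: pd.DataFrame,
    mchh: pd.DataFrame,
    thr: StateThresholds | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`classify_state` over genes x accessions frames."""
    thr = thr or StateThresholds()
    if not (mcg.shape == mchg.shape == mchh.shape):
        raise ValueError("context matrices must share shape")
    cg = mcg.to_numpy(dtype=float)
    chg = mchg.to_numpy(dtype=float)
    chh = mchh.to_numpy(dtype=float)
    noncg_ok = (chg <= thr.chg_max) & (chh <= thr.chh_max)
    missing = np.isnan(cg) | np.isnan(chg) | np.isnan(chh)
    out = np.full(cg.shape, UNCLASSIFIED, dtype=object)
    with np.errstate(invalid="ignore"):
        out[noncg_ok & (cg <= thr.um_cg_max)] = UM
        out[noncg_ok & (cg >= thr.gbm_cg_min)] = GBM
    out[missing] = UNCLASSIFIED
    return pd.DataFrame(out, index=mcg.index, columns=mcg.columns)


def classify_population(
    states: pd.DataFrame,
    gbm_nv_min: int = 700,
    im_lo: int = 100,
    im_hi: int = 700,
) -> pd.DataFrame:
    """Per-gene stability class from the genes x accessions state matrix.

    Returns n_gbm, n_um, and klass per gene. GBM_NV: n_gbm > gbm_nv_min;
    UM_NV: n_um > gbm_nv_min; IM_NV: im_lo <= n_gbm <= im_hi; stable
    classes are checked first.
    """
    n_gbm = (states == GBM).sum(axis=1)
    n_um = (states == UM).sum(axis=1)
    klass = pd.Series("OTHER", index=states.index, name="klass", dtype=object)
    im = (n_gbm >= im_lo) & (n_gbm <= im_hi)
    klass[im] = "IM_NV"
    klass[n_gbm > gbm_nv_min] = "GBM_NV"
    klass[n_um > gbm_nv_min] = "UM_NV"
    return pd.DataFrame({"n_gbm": n_gbm, "n_um": n_um, "klass": klass})


def class_percentages(classes: pd.DataFrame | pd.Series, n_annotated: int) -> pd.DataFrame:
    """Percent of annotated genes per class: rounded integer and raw fraction."""
    if n_annotated <= 0:
        raise ValueError("n_annotated must be positive")
    klass = classes["klass"] if isinstance(classes, pd.DataFrame) else classes
    counts = klass.value_counts()
    rows = []
    for name in CLASSES:
        count = int(counts.get(name, 0))
        frac = count / n_annotated
        rows.append((name, count, frac, int(round(100 * frac))))
    return pd.DataFrame(rows, columns=["klass", "count", "fraction", "percent"]).set_index("klass")


def percentages_from_counts(counts: dict[str, int], n_annotated: int) -> dict[str, int]:
    """Rounded percentages for externally tabulated per-class gene counts."""
    if n_annotated <= 0:
        raise ValueError("n_annotated must be positive")
    return {k: int(round(100 * v / n_annotated)) for k, v in counts.items()}


def read_population_long(path) -> dict[str, pd.DataFrame]:
    """Read a long-format panel TSV (gene_id, accession, mCG, mCHG, mCHH)
    into the three genes x accessions level frames."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "accession", "mCG", "mCHG", "mCHH"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    return {
        ctx: df.pivot(index="gene_id", columns="accession", values=ctx)
        for ctx in ("mCG", "mCHG", "mCHH")
    }


def write_population_long(levels: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for ctx in ("mCG", "mCHG", "mCHH"):
        long = levels[ctx].stack()
        long.name = ctx
        frames.append(long)
    out = pd.concat(frames, axis=1).reset_index()
    out.columns = ["gene_id", "accession", "mCG", "mCHG", "mCHH"]
    out.to_csv(path, sep="\t", index=False)


def regulator_demethylation_status(
    mcg: pd.DataFrame,
    gene_ids,
    demeth_max: float = 0.05,
    gbm_min: float = 0.10,
) -> pd.DataFrame:
    """Accession-level CG status (DEMETHYLATED/GBM/INTERMEDIATE) per gene.

    Used to ask, per accession, how many of a small set of regulator genes
    are demethylated (mean gene mCG < demeth_max) versus body-methylated
    (mCG >= gbm_min).
    """
    missing = [g for g in gene_ids if g not in mcg.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")
    sub = mcg.loc[list(gene_ids)].to_numpy(dtype=float)
    out = np.full(sub.shape, "INTERMEDIATE", dtype=object)
    with np.errstate(invalid="ignore"):
        out[sub < demeth_max] = "DEMETHYLATED"
        out[sub >= gbm_min] = "GBM"
    out[np.isnan(sub)] = "INTERMEDIATE"
    return pd.DataFrame(out, index=list(gene_ids), columns=mcg.columns)
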