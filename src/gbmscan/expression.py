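"""Permutation-calibrated differential expression and priming categories.

The differential-expression statistic follows the microarray procedure:
per gene, (1) a Welch (unequal-variance) t statistic and (2) the log2
median difference between the two groups are computed; (3) empirical null
distributions of both statistics are built by randomly permuting all
sample labels of the contrast and recomputing both statistics for every
gene; (4) each gene's adjusted p-values are two-sided empirical p-values
against the pooled (genes x permutations) nulls; (5) the two p-values are
combined with the equal-weight Liptak-Stouffer Z method.

DEG flags: strict = combined p <= 0.01 AND t p <= 0.1 AND |log2 median
difference| >= 0.58 (1.5-fold); loose = combined p <= 0.01 (captures
subtle but significant changes).

Note the two component statistics are computed on the same data and are
positively correlated, so the independence-assuming combination is
anti-conservative under a global null; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .stats import empirical_p_vec, stouffer_combine_vec

STRICT_P_COMBINED = 0.01
STRICT_P_T = 0.1
STRICT_MIN_MD = 0.58  # log2(1.5-fold)


@dataclass
class DEGThresholds:
    p_combined: float = STRICT_P_COMBINED
    p_t: float = STRICT_P_T
    min_abs_md: float = STRICT_MIN_MD


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom = np.sqrt(va / a.shape[1] + vb / b.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)


def _pair_stats(x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    a, b = x[:, idx_a], x[:, idx_b]
    t = _welch_t(a, b)
    md = np.median(a, axis=1) - np.median(b, axis=1)
    return t, md


def deg_test(
    matrix: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    thresholds: DEGThresholds | None = None,
) -> pd.DataFrame:
    """Differential expression of group_a vs group_b (log2 matrix).

    Returns one row per gene: t_stat, log2_md, p_t, p_md, p_combined,
    is_deg_strict, is_deg_loose. Positive t / log2_md mean higher
    expression in ``group_a``. Fully reproducible for a fixed seed and
    invariant to gene order.
    """
    thr = thresholds or DEGThresholds()
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    cols = list(group_a) + list(group_b)
    missing = [c for c in cols if c not in values.columns]
    if missing:
        raise ValueError(f"unknown sample columns: {missing}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; empirical p-values will be coarse")
    x = values[cols].to_numpy(dtype=float)
    n_a = len(group_a)
    n = x.shape[1]
    idx_a, idx_b = np.arange(n_a), np.arange(n_a, n)
    t_obs, md_obs = _pair_stats(x, idx_a, idx_b)

    rng = np.random.default_rng(seed)
    null_t = np.empty((n_perm, x.shape[0]))
    null_md = np.empty((n_perm, x.shape[0]))
    for i in range(n_perm):
        perm = rng.permutation(n)
        null_t[i], null_md[i] = _pair_stats(x, perm[:n_a], perm[n_a:])
    abs_null_t = np.sort(np.abs(null_t), axis=None)
    abs_null_md = np.sort(np.abs(null_md), axis=None)
    p_t = empirical_p_vec(t_obs, abs_null_t)
    p_md = empirical_p_vec(md_obs, abs_null_md)
    p_combined = stouffer_combine_vec([p_t, p_md])

    out = pd.DataFrame(
        {
            "t_stat": t_obs,
            "log2_md": md_obs,
            "p_t": p_t,
            "p_md": p_md,
            "p_combined": p_combined,
        },
        index=values.index.copy(),
    )
    out["is_deg_loose"] = out["p_combined"] <= thr.p_combined
    out["is_deg_strict"] = (
        out["is_deg_loose"]
        & (out["p_t"] <= thr.p_t)
        & (out["log2_md"].abs() >= thr.min_abs_md)
    )
    return out


def deg_test_contrast(
    matrix: ExpressionMatrix,
    genotype_a: str,
    genotype_b: str,
    condition: str,
    n_perm: int = 1000,
    seed: int = 0,
    thresholds: DEGThresholds | None = None,
) -> pd.DataFrame:
    """``deg_test`` with groups selected by genotype/condition labels."""
    a = matrix.columns_for(genotype_a, condition)
    b = matrix.columns_for(genotype_b, condition)
    if not a or not b:
        raise ValueError(f"no samples for contrast {genotype_a} vs {genotype_b} @ {condition}")
    return deg_test(matrix, a, b, n_perm=n_perm, seed=seed, thresholds=thresholds)


# -- priming categorization ------------------------------------------------

PRIMING_CATEGORIES = ("DDM1_HYPER", "DDM1_SUP", "BASAL_UP", "BASAL_DOWN", "NONE")


def categorize_priming(
    deg_mock: pd.DataFrame, deg_basubdc: pd.DataFrame
) -> pd.Series:
    """Expression-pattern category per gene from two mutant-vs-wildtype contrasts.

    Basal categories take precedence: a strict DEG under mock is BASAL_UP or
    BASAL_DOWN by sign. Genes not DEG under mock but strict DEG under
    BAsubDC are DDM1_HYPER (up) or DDM1_SUP (down); everything else NONE.
    """
    idx = deg_mock.index
    if not idx.equals(deg_basubdc.index):
        raise ValueError("contrast tables must cover the same genes")
    mock_strict = deg_mock["is_deg_strict"]
    mock_up = mock_strict & (deg_mock["log2_md"] > 0)
    mock_down = mock_strict & (deg_mock["log2_md"] < 0)
    dc_strict = deg_basubdc["is_deg_strict"]
    dc_up = dc_strict & (deg_basubdc["log2_md"] > 0)
    dc_down = dc_strict & (deg_basubdc["log2_md"] < 0)
    out = pd.Series("NONE", index=idx, name="priming_category")
    out[~mock_strict & dc_up] = "DDM1_HYPER"
    out[~mock_strict & dc_down] = "DDM1_SUP"
    out[mock_up] = "BASAL_UP"
    out[mock_down] = "BASAL_DOWN"
    return out


def subtle_groups(
    matrix: ExpressionMatrix,
    wildtype_label: str = "wildtype",
    condition_a: str = "BAsubDC",
    condition_b: str = "mock",
    n_perm: int = 1000,
    seed: int = 0,
    max_p: float = 0.01,
    fc_estimator: str = "mean",
) -> pd.DataFrame:
    """Subtly activated / suppressed genes in the wild type (BAsubDC vs mock).

    SUBTLE_UP: 0 < log2FC <= 1 and combined p <= 0.01; SUBTLE_DOWN:
    -1 <= log2FC < 0 and combined p <= 0.01. log2FC is the mean (default)
    or median difference of log2 values, condition_a - condition_b.
    """
    a = matrix.columns_for(wildtype_label, condition_a)
    b = matrix.columns_for(wildtype_label, condition_b)
    if not a or not b:
        raise ValueError("missing wildtype samples for the subtle-group contrast")
    deg = deg_test(matrix, a, b, n_perm=n_perm, seed=seed)
    if fc_estimator == "mean":
        fc = matrix.values[a].mean(axis=1) - matrix.values[b].mean(axis=1)
    elif fc_estimator == "median":
        fc = deg["log2_md"]
    else:
        raise ValueError(f"unknown fc_estimator {fc_estimator!r}")
    sig = deg["p_combined"] <= max_p
    group = pd.Series("NONE", index=deg.index, name="subtle_group")
    group[sig & (fc > 0) & (fc <= 1)] = "SUBTLE_UP"
    group[sig & (fc < 0) & (fc >= -1)] = "SUBTLE_DOWN"
    return pd.DataFrame({"log2_fc": fc, "p_combined": deg["p_combined"], "subtle_group": group})
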