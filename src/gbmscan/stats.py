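"""Shared statistical primitives for the methylation/expression pipeline.

Every downstream stage funnels through the five operations here: Fisher's
exact test on 2x2 methylation count tables, empirical p-values against
permutation nulls, the Liptak-Stouffer Z combination, quantile
normalization of expression matrices, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact",
    "fisher_greater_vec",
    "empirical_p",
    "stouffer_combine",
    "quantile_normalize",
    "bh_fdr",
]


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValueError("contingency table entries must be integers")
        arr = rounded.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    return arr


def fisher_exact(table, sidedness: str = "greater") -> float:
    """Exact hypergeometric tail probability for a 2x2 count table.

    ``table`` is ``[[a, b], [c, d]]`` with row 1 = focal sample
    (methylated, unmethylated) and row 2 = baseline. ``sidedness`` is
    ``"greater"`` (row 1 more methylated than the baseline) or
    ``"two_sided"``. Degenerate tables — any row or column margin of
    zero — carry no evidence and return 1.0.
    """
    arr = _as_table(table)
    if sidedness not in ("greater", "two_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    alternative = "greater" if sidedness == "greater" else "two-sided"
    return float(sps.fisher_exact(arr, alternative=alternative)[1])


def fisher_greater_vec(a, b, c, d) -> np.ndarray:
    """Vectorized one-sided ("greater") Fisher test for many 2x2 tables.

    Same tail as ``fisher_exact(..., "greater")``: with fixed margins the
    count ``a`` is hypergeometric, and the p-value is P(X >= a). Degenerate
    tables return 1. Used by the window caller, where tens of thousands of
    tables are tested at once.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    with np.errstate(invalid="ignore"):
        p = sps.hypergeom.sf(a - 1, total, col1, row1)
    degenerate = (row1 == 0) | (c + d == 0) | (col1 == 0) | (b + d == 0)
    p = np.where(degenerate, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def empirical_p(observed: float, null_samples, tail: str = "right") -> float:
    """Permutation p-value with a +1 pseudocount: (1 + k) / (1 + N).

    ``k`` counts null draws at least as extreme as ``observed`` under
    ``tail`` ("right", "left", or "two_sided" on absolute values). The
    pseudocount guarantees p > 0; values lie on the grid k/(N+1).
    """
    null = np.asarray(null_samples, dtype=float).ravel()
    if null.size == 0:
        raise ValueError("null_samples must be non-empty")
    if tail == "right":
        k = int(np.count_nonzero(null >= observed))
    elif tail == "left":
        k = int(np.count_nonzero(null <= observed))
    elif tail == "two_sided":
        k = int(np.count_nonzero(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + null.size)


def empirical_p_vec(observed, sorted_abs_null: np.ndarray) -> np.ndarray:
    """Two-sided empirical p for many observations against one pooled null.

    ``sorted_abs_null`` must be ``np.sort(np.abs(null))``; p follows the
    same (1+k)/(1+N) rule as :func:`empirical_p`.
    """
    obs = np.abs(np.asarray(observed, dtype=float))
    n = sorted_abs_null.size
    if n == 0:
        raise ValueError("null must be non-empty")
    k = n - np.searchsorted(sorted_abs_null, obs, side="left")
    return (1 + k) / (1 + n)


def stouffer_combine(p_values, weights=None) -> float:
    """Liptak-Stouffer combination of one-sided p-values.

    Z = sum(w_i * Phi^-1(1 - p_i)) / sqrt(sum(w_i^2)); returns 1 - Phi(Z).
    Weights default to 1 (equal). A single p-value is returned unchanged
    (the transform is the identity for one component).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p-values must lie strictly in (0, 1)")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != p.shape:
            raise ValueError("weights must match p_values in length")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    z = float(np.sum(w * sps.norm.isf(p)) / np.sqrt(np.sum(w**2)))
    return float(sps.norm.sf(z))


def stouffer_combine_vec(p_columns: Sequence[np.ndarray]) -> np.ndarray:
    """Equal-weight Stouffer combination applied row-wise to aligned arrays."""
    cols = [np.asarray(p, dtype=float) for p in p_columns]
    z = np.sum([sps.norm.isf(p) for p in cols], axis=0) / np.sqrt(len(cols))
    return sps.norm.sf(z)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of per-rank means.

    After normalization all columns share identical sorted values (the mean
    across columns of the k-th smallest entries). Ties within a column get
    the mean of the rank-mean values they span (average-rank convention),
    which makes the operation idempotent. Labels are preserved.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if matrix.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    x = matrix.to_numpy(dtype=float)
    rank_means = np.sort(x, axis=0).mean(axis=1)
    # average ranks, 0-based; half-integer ranks interpolate adjacent means
    ranks = matrix.rank(axis=0, method="average").to_numpy() - 1.0
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    out = (rank_means[lo] + rank_means[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in the p-value ranks)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
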