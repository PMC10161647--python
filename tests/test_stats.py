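"""Unit and property tests for the shared statistical primitives."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gbmscan.stats import (
    bh_fdr,
    empirical_p,
    empirical_p_vec,
    fisher_exact,
    fisher_greater_vec,
    quantile_normalize,
    stouffer_combine,
)

# -- Fisher's exact test ---------------------------------------------------

_COMB = [[math.comb(n, k) for k in range(61)] for n in range(61)]


def fisher_greater_oracle(a, b, c, d):
    """Brute-force hypergeometric enumeration: P(X >= a) with fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or (c + d) == 0 or (b + d) == 0:
        return 1.0
    denom = _COMB[n][r1]
    num = sum(
        _COMB[c1][k] * _COMB[n - c1][r1 - k]
        for k in range(a, min(r1, c1) + 1)
    )
    return num / denom


def test_fisher_known_values():
    # all 5 methylated vs none: one table is as extreme -> 1 / C(10,5)
    assert fisher_exact([[5, 0], [0, 5]], "greater") == pytest.approx(1 / 252, rel=1e-9)
    # degenerate margins carry no evidence
    assert fisher_exact([[0, 0], [0, 0]], "greater") == 1.0
    assert fisher_exact([[0, 0], [0, 0]], "two_sided") == 1.0
    assert fisher_exact([[3, 0], [2, 0]], "greater") == 1.0
    # the observed table is the mode: everything is at least as extreme
    assert fisher_exact([[3, 3], [3, 3]], "two_sided") == 1.0


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_exact([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_exact([[1, 2], [3, 4]], "less")


@given(
    st.tuples(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
)
@settings(max_examples=200, deadline=None)
def test_fisher_matches_enumeration(table):
    a, b, c, d = table
    expected = fisher_greater_oracle(a, b, c, d)
    assert fisher_exact([[a, b], [c, d]], "greater") == pytest.approx(expected, abs=1e-12)


def test_vectorized_fisher_agrees_with_scalar():
    rng = np.random.default_rng(0)
    abcd = rng.integers(0, 30, size=(500, 4))
    vec = fisher_greater_vec(*abcd.T)
    for (a, b, c, d), p in zip(abcd, vec):
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]], "greater"), abs=1e-10)


# -- empirical permutation p-values ---------------------------------------


def test_empirical_p_examples():
    assert empirical_p(10, list(range(1, 10)), "right") == pytest.approx(0.1)
    null = [-2.0, -1.0, 0.0, 1.0, 2.0]
    assert empirical_p(0.0, null, "two_sided") == 1.0
    assert empirical_p(-10, list(range(1, 10)), "left") == pytest.approx(0.1)
    with pytest.raises(ValueError):
        empirical_p(1.0, [], "right")
    with pytest.raises(ValueError):
        empirical_p(1.0, [1.0], "both")


@given(st.floats(-5, 5), st.integers(1, 50))
@settings(max_examples=100, deadline=None)
def test_empirical_p_on_grid_and_positive(obs, n):
    rng = np.random.default_rng(n)
    null = rng.normal(size=n)
    for tail in ("right", "left", "two_sided"):
        p = empirical_p(obs, null, tail)
        assert 0 < p <= 1
        assert round(p * (n + 1)) == pytest.approx(p * (n + 1))  # grid k/(N+1)


def test_empirical_p_uniform_under_null():
    """Observed drawn from the null distribution gives ~uniform p-values."""
    rng = np.random.default_rng(42)
    null = np.sort(np.abs(rng.normal(size=5000)))
    obs = rng.normal(size=2000)
    p = empirical_p_vec(obs, null)
    d, _ = sps.kstest(p, "uniform")
    assert d < 0.05


# -- Liptak-Stouffer combination -------------------------------------------


def test_stouffer_known_values():
    assert stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
    assert stouffer_combine([0.07]) == pytest.approx(0.07, abs=1e-12)
    # agreement with the reference implementation
    for pvals in ([0.01, 0.2, 0.6], [0.3, 0.3, 0.3, 0.9]):
        _, ref = sps.combine_pvalues(pvals, method="stouffer")
        assert stouffer_combine(pvals) == pytest.approx(ref, rel=1e-10)
    # weights are normalized by sqrt(sum w^2)
    _, ref = sps.combine_pvalues([0.02, 0.4], method="stouffer", weights=[2.0, 1.0])
    assert stouffer_combine([0.02, 0.4], [2.0, 1.0]) == pytest.approx(ref, rel=1e-10)


@pytest.mark.parametrize("p,increasing", [(0.01, False), (0.9, True)])
def test_stouffer_monotone_in_replication(p, increasing):
    """Replicating the same evidence strengthens it monotonically."""
    combined = [stouffer_combine([p] * k) for k in range(1, 6)]
    diffs = np.diff(combined)
    assert (diffs > 0).all() if increasing else (diffs < 0).all()


def test_stouffer_rejects_boundary_p():
    for bad in ([0.0, 0.5], [0.5, 1.0], []):
        with pytest.raises(ValueError):
            stouffer_combine(bad)


# -- quantile normalization ------------------------------------------------


def test_quantile_normalize_hand_example():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    out = quantile_normalize(df)
    expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
    pd.testing.assert_frame_equal(out, expected)


def test_quantile_normalize_preserves_identical_distributions():
    df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
    out = quantile_normalize(df)
    pd.testing.assert_frame_equal(out, df.astype(float))


@given(st.integers(2, 12), st.integers(2, 6), st.integers(0, 10))
@settings(max_examples=60, deadline=None)
def test_quantile_normalize_properties(n_rows, n_cols, seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n_rows, n_cols)))
    out = quantile_normalize(df)
    # defining property: all columns share identical sorted values
    sorted_cols = np.sort(out.to_numpy(), axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]])
    # idempotence
    pd.testing.assert_frame_equal(quantile_normalize(out), out)


def test_quantile_normalize_rejects_bad_input():
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame())
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"a": [1.0, np.nan]}))


# -- Benjamini-Hochberg ----------------------------------------------------


def test_bh_fdr_examples():
    assert np.allclose(bh_fdr([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bh_fdr([0.07]), [0.07])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=100, deadline=None)
def test_bh_fdr_dominates_p_and_bounded(pvals):
    q = bh_fdr(pvals)
    assert (q >= np.asarray(pvals) - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    # q is monotone in the p-value ranks
    order = np.argsort(pvals)
    assert (np.diff(q[order]) >= -1e-12).all()
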