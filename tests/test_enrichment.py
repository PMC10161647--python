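"""Overlap/term enrichment, metaprofiles, and feature clustering."""

import numpy as np
import pandas as pd
import pytest

from gbmscan.enrichment import (
    cluster_features,
    metaprofile,
    overlap_enrichment,
    term_enrichment,
)
from gbmscan.io import GeneModel
from gbmscan.stats import fisher_exact

from conftest import make_sample, uniform_sample


UNIVERSE = [f"g{i}" for i in range(10000)]


class TestOverlapEnrichment:
    def test_tenfold_enrichment_arithmetic(self):
        a = UNIVERSE[:100]
        b = UNIVERSE[90:190]  # overlap 10
        res = overlap_enrichment(a, b, UNIVERSE)
        assert res.expected == pytest.approx(1.0)
        assert res.ratio == pytest.approx(10.0)
        assert res.observed_overlap == 10
        assert res.p < 1e-6

    def test_ratio_times_expected_equals_observed(self):
        rng = np.random.default_rng(0)
        a = list(rng.choice(UNIVERSE, 300, replace=False))
        b = list(rng.choice(UNIVERSE, 500, replace=False))
        res = overlap_enrichment(a, b, UNIVERSE)
        assert res.ratio * res.expected == pytest.approx(res.observed_overlap)

    def test_self_overlap_is_unity(self):
        res = overlap_enrichment(UNIVERSE, UNIVERSE, UNIVERSE)
        assert res.ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_fisher_p_matches_equivalent_table(self):
        a, b = UNIVERSE[:50], UNIVERSE[40:120]
        res = overlap_enrichment(a, b, UNIVERSE)
        table = [[10, 40], [70, 10000 - 50 - 80 + 10]]
        assert res.p == pytest.approx(fisher_exact(table, "greater"), rel=1e-9)

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(["x"], UNIVERSE[:5], UNIVERSE)


class TestTermEnrichment:
    def test_perfect_term_reported(self):
        query = UNIVERSE[:50]
        annot = {"perfect": query, "background": UNIVERSE[50:5050]}
        out = term_enrichment(query, annot, UNIVERSE)
        assert list(out["term"]) == ["perfect"]
        assert out["fold"].iloc[0] == pytest.approx(len(UNIVERSE) / 50)

    def test_disjoint_term_not_reported(self):
        out = term_enrichment(UNIVERSE[:50], {"t": UNIVERSE[100:200]}, UNIVERSE)
        assert len(out) == 0

    def test_fold_filter_drops_weak_enrichment(self):
        # overlap 30 of 50 against a term holding 40% of the universe: fold 1.5
        term = UNIVERSE[:30] + UNIVERSE[100:4070]
        out = term_enrichment(UNIVERSE[:50], {"t": term}, UNIVERSE)
        assert len(out) == 0

    def test_hypergeometric_p_matches_fisher(self):
        query, term = UNIVERSE[:60], UNIVERSE[30:130]
        out = term_enrichment(query, {"t": term}, UNIVERSE, fdr_max=1.1, fold_min=0)
        overlap = 30
        table = [
            [overlap, len(query) - overlap],
            [len(term) - overlap, 10000 - len(query) - len(term) + overlap],
        ]
        assert out["p"].iloc[0] == pytest.approx(fisher_exact(table, "greater"), rel=1e-9)


class TestMetaprofile:
    GENES = [GeneModel("g1", "chr1", "+", 2000, 4000)]

    def test_uniform_methylation_gives_flat_profile(self):
        s = uniform_sample(start=0, end=6000, spacing=10, level=0.5, depth=20)
        prof = metaprofile(s, self.GENES, "CG", flank_bp=1000)
        covered = prof[prof["n_total"] > 0]
        assert np.allclose(covered["level"], 0.5)

    def test_body_only_methylation_leaves_flanks_empty(self):
        rows = [("chr1", p, "+", "CG", 10, 10) for p in range(2000, 4000, 10)]
        s = make_sample(rows)
        prof = metaprofile(s, self.GENES, "CG", flank_bp=1000)
        assert (prof.loc[prof["zone"] != "body", "n_total"] == 0).all()
        assert np.allclose(prof.loc[prof["zone"] == "body", "level"], 1.0)

    def test_single_bin_pools_to_global_level(self):
        s = uniform_sample(start=2000, end=4000, spacing=10, level=0.3, depth=10)
        prof = metaprofile(s, self.GENES, "CG", flank_bp=100, n_flank_bins=1, n_body_bins=1)
        body = prof[prof["zone"] == "body"].iloc[0]
        df = s.cytosines
        inside = df[(df["pos"] >= 2000) & (df["pos"] < 4000)]
        assert body["n_total"] == inside["n_total"].sum()
        assert body["level"] == pytest.approx(
            inside["n_meth"].sum() / inside["n_total"].sum()
        )

    def test_minus_strand_gene_is_flipped(self):
        gene = [GeneModel("g1", "chr1", "-", 2000, 4000)]
        # methylation only near the 3' end in genome coordinates = 5' of the gene
        rows = [("chr1", p, "+", "CG", 10, 10) for p in range(3900, 4000, 10)]
        rows += [("chr1", p, "+", "CG", 0, 10) for p in range(2000, 3900, 10)]
        prof = metaprofile(make_sample(rows), gene, "CG", flank_bp=500)
        body = prof[prof["zone"] == "body"].reset_index(drop=True)
        assert body["level"].iloc[0] > 0.9  # first body bin in gene orientation
        assert body["level"].iloc[-1] < 0.1


class TestClustering:
    def test_two_separated_blobs_split_perfectly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.2, (30, 5))
        b = rng.normal(3, 0.2, (40, 5))
        df = pd.DataFrame(np.vstack([a, b]), index=[f"g{i:03d}" for i in range(70)])
        labels = cluster_features(df, k=2)
        assert labels.iloc[:30].nunique() == 1
        assert labels.iloc[30:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_rows_form_single_cluster(self):
        df = pd.DataFrame(np.ones((10, 4)), index=[f"g{i}" for i in range(10)])
        labels = cluster_features(df, k=2)
        assert (labels == 1).all()

    def test_labels_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(4, 0.3, (20, 4))])
        idx = [f"g{i:03d}" for i in range(40)]
        df = pd.DataFrame(x, index=idx)
        shuffled = df.sample(frac=1, random_state=3)
        a = cluster_features(df, k=2)
        b = cluster_features(shuffled, k=2)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_features(pd.DataFrame({"a": [1.0, np.nan]}))
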