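"""Window calling, merging, and TEM/GBM region classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbmscan.io import GenomicInterval
from gbmscan.regions import (
    ClassThresholds,
    call_significant_windows,
    classify_regions,
    merge_windows,
    read_regions_bed,
    region_level,
    union_intervals,
)
from gbmscan.io import write_regions_bed
from gbmscan.stats import fisher_exact

from conftest import make_sample, uniform_sample


def _pair(level_sample, level_base, depth=50, context="CHG", n_sites=5):
    rows_s, rows_b = [], []
    for i in range(n_sites):
        pos = 10 + i * 8
        rows_s.append(("chr1", pos, "+", context, int(level_sample * depth), depth))
        rows_b.append(("chr1", pos, "+", context, int(level_base * depth), depth))
    genotype = "ddcc_like" if context in ("CHG", "CHH") else "met1_like"
    return make_sample(rows_s), make_sample(rows_b, genotype=genotype)


class TestWindowCalling:
    def test_fully_methylated_vs_empty_baseline_is_significant(self):
        sample, baseline = _pair(1.0, 0.0, depth=10, context="CHG")
        wins = call_significant_windows(sample, baseline, "CHG", p_cutoff=1e-4)
        assert len(wins) == 1
        assert (wins.loc[0, "start"], wins.loc[0, "end"]) == (0, 50)
        # one-sided p equals the single most-extreme-table probability
        expected = fisher_exact([[50, 0], [0, 50]], "greater")
        assert wins.loc[0, "p"] == pytest.approx(expected, rel=1e-6)

    def test_identical_counts_not_significant(self):
        sample, baseline = _pair(0.5, 0.5, context="CHG")
        wins = call_significant_windows(sample, baseline, "CHG", p_cutoff=1e-4)
        assert len(wins) == 0

    def test_zero_coverage_window_not_significant(self):
        sample = make_sample([("chr1", 10, "+", "CHG", 0, 0), ("chr1", 20, "+", "CHG", 0, 0)])
        baseline = make_sample([("chr1", 10, "+", "CHG", 0, 20)], genotype="ddcc_like")
        wins = call_significant_windows(sample, baseline, "CHG", p_cutoff=0.5)
        assert len(wins) == 0

    def test_single_covered_site_never_called(self):
        sample = make_sample([("chr1", 10, "+", "CHG", 50, 50)])
        baseline = make_sample([("chr1", 10, "+", "CHG", 0, 50)], genotype="ddcc_like")
        wins = call_significant_windows(sample, baseline, "CHG", p_cutoff=1e-4)
        assert len(wins) == 0

    def test_wrong_baseline_genotype_rejected(self):
        sample, baseline = _pair(1.0, 0.0, context="CHG")  # baseline is ddcc_like
        with pytest.raises(ValueError, match="met1_like"):
            call_significant_windows(sample, baseline, "CG", p_cutoff=1e-14)


class TestMerging:
    def test_gap_strictly_below_500_merges(self):
        w = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 499, 549)]
        merged = merge_windows(w, 500)
        assert [(m.start, m.end) for m in merged] == [(0, 549)]

    def test_gap_of_exactly_500_does_not_merge(self):
        w = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 550, 600)]
        assert len(merge_windows(w, 500)) == 2

    def test_single_window_unchanged(self):
        w = [GenomicInterval("chr1", 100, 150)]
        assert [(m.start, m.end) for m in merge_windows(w, 500)] == [(100, 150)]

    def test_chromosomes_never_merge(self):
        w = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr2", 60, 110)]
        assert len(merge_windows(w, 500)) == 2

    @given(st.lists(st.integers(0, 40), min_size=1, max_size=15), st.integers(0, 20))
    @settings(max_examples=80, deadline=None)
    def test_merge_order_invariant_and_disjoint(self, starts, seed):
        ivs = [GenomicInterval("chr1", s * 60, s * 60 + 50) for s in sorted(set(starts))]
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(ivs))
        a = merge_windows(ivs, 100)
        b = merge_windows(shuffled, 100)
        assert [(m.start, m.end) for m in a] == [(m.start, m.end) for m in b]
        for prev, nxt in zip(a, a[1:]):
            assert prev.end < nxt.start  # disjoint, sorted


class TestRegionLevel:
    def test_fully_methylated(self):
        s = uniform_sample(level=1.0, depth=10)
        level, m, t = region_level(s, GenomicInterval("chr1", 0, 1000), "CG")
        assert level == 1.0 and m == t

    def test_no_covered_cytosines_flagged_as_zero_total(self):
        s = uniform_sample(level=1.0)
        level, _, total = region_level(s, GenomicInterval("chr1", 5000, 6000), "CG")
        assert level == 0.0 and total == 0

    def test_pooled_arithmetic(self):
        s = make_sample(
            [("chr1", 10, "+", "CG", 10, 40), ("chr1", 20, "+", "CG", 20, 60)]
        )
        level, m, t = region_level(s, GenomicInterval("chr1", 0, 100), "CG")
        assert (m, t) == (30, 100) and level == pytest.approx(0.30)


def _levels_sample(mcg, mchg, mchh, start=0, end=600):
    rows = []
    for i, pos in enumerate(range(start + 5, end, 15)):
        rows.append(("chr1", pos, "+", "CG", int(round(mcg * 100)), 100))
    for pos in range(start + 7, end, 20):
        rows.append(("chr1", pos, "+", "CHG", int(round(mchg * 100)), 100))
    for pos in range(start + 9, end, 10):
        rows.append(("chr1", pos, "+", "CHH", int(round(mchh * 100)), 100))
    return make_sample(rows)


class TestClassification:
    def test_cg_region_with_noncg_overlap_and_high_levels_is_tem(self):
        sample = _levels_sample(0.5, 0.2, 0.05)
        cg = [GenomicInterval("chr1", 0, 600)]
        chg = [GenomicInterval("chr1", 100, 300)]
        out = classify_regions(cg, chg, [], sample)
        assert [r.klass for r in out] == ["TEM_LIKE"]
        assert out[0].mean_mcg == pytest.approx(0.5)

    def test_cg_only_region_is_gbm(self):
        sample = _levels_sample(0.3, 0.01, 0.005)
        out = classify_regions([GenomicInterval("chr1", 0, 600)], [], [], sample)
        assert [r.klass for r in out] == ["GBM_LIKE"]

    def test_low_cg_region_dropped(self):
        sample = _levels_sample(0.08, 0.01, 0.005)
        out = classify_regions([GenomicInterval("chr1", 0, 600)], [], [], sample)
        assert out == []

    def test_tem_candidate_failing_level_thresholds_dropped(self):
        # overlaps nonCG but CHH level below the TEM floor and above the GBM cap
        sample = _levels_sample(0.5, 0.2, 0.01)
        out = classify_regions(
            [GenomicInterval("chr1", 0, 600)], [GenomicInterval("chr1", 0, 600)], [], sample
        )
        assert out == []

    def test_classes_are_disjoint_and_respect_invariants(self, methylome_sim):
        _, samples, _ = methylome_sim
        from gbmscan.regions import call_regions

        out = call_regions(samples["wildtype"], samples["met1_like"], samples["ddcc_like"])
        thr = ClassThresholds()
        for r in out:
            if r.klass == "TEM_LIKE":
                assert r.mean_mcg >= thr.tem_cg_min
                assert r.mean_mchg >= thr.tem_chg_min
                assert r.mean_mchh >= thr.tem_chh_min
            else:
                assert r.mean_mcg >= thr.gbm_cg_min
                assert r.mean_mchg <= thr.gbm_chg_max
                assert r.mean_mchh <= thr.gbm_chh_max

    def test_genome_with_only_gbm_regions_yields_no_tem_calls(self):
        from gbmscan.regions import call_regions
        from gbmscan.simulate import MethylomeConfig, simulate_methylome

        cfg = MethylomeConfig(seed=31, n_genes_per_chrom=20, n_tem=0, n_gbm=10)
        samples, _ = simulate_methylome(cfg)
        out = call_regions(samples["wildtype"], samples["met1_like"], samples["ddcc_like"])
        assert out and all(r.klass == "GBM_LIKE" for r in out)


def test_union_intervals_coalesces_touching():
    u = union_intervals(
        [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 100, 200)]
    )
    assert [(i.start, i.end) for i in u] == [(0, 200)]


def test_regions_bed_round_trip(tmp_path, small_methylome_sim):
    from gbmscan.regions import call_regions

    _, samples, _ = small_methylome_sim
    regions = call_regions(samples["wildtype"], samples["met1_like"], samples["ddcc_like"])
    p = tmp_path / "regions.bed"
    write_regions_bed(regions, p, header="test")
    back = read_regions_bed(p)
    assert len(back) == len(regions)
    assert [r.klass for r in back] == [r.klass for r in regions]
    assert [r.interval.start for r in back] == [r.interval.start for r in regions]
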