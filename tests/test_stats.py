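"""Median splits, fold/rank-sum association, Fisher exact and Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from focalamp.stats import (ContingencyTable2x2, breakpoint_fold_and_test,
                            fisher_exact_two_sided, mann_whitney,
                            region_element_enrichment, split_by_median)
from tests.oracles import fisher_enumeration_oracle, mw_enumeration_oracle


def window_table(contents, eligible=None):
    n = len(contents)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 50_000,
        "end": (np.arange(n) + 1) * 50_000,
        "eligible": eligible if eligible is not None else [True] * n,
        "content": contents,
    })


class TestMedianSplit:
    def test_even_split_around_median(self):
        split = split_by_median(window_table([1, 2, 3, 4]), "content")
        assert split.median == 2.5
        assert list(split.above) == [False, False, True, True]
        assert not split.degenerate

    def test_all_equal_is_degenerate(self):
        split = split_by_median(window_table([5, 5, 5]), "content")
        assert split.degenerate
        assert not split.above.any()

    def test_strict_rule_balances_up_to_ties(self, rng):
        contents = rng.integers(0, 50, 1000).astype(float)
        split = split_by_median(window_table(list(contents)), "content")
        n_above = int(split.above.sum())
        n_strictly_below = int((contents < split.median).sum())
        n_ties = int((contents == split.median).sum())
        assert abs(n_above - n_strictly_below) <= n_ties
        assert n_above + n_strictly_below + n_ties == 1000

    def test_scope_restricts_median(self):
        table = window_table([1, 2, 3, 4, 100, 200])
        scope = np.array([True] * 4 + [False] * 2)
        split = split_by_median(table, "content", scope=scope)
        assert split.median == 2.5
        assert not split.above[4:].any()  # outside scope never labelled


class TestFoldAndTest:
    def test_fold_of_two(self):
        table = window_table([1.0] * 6 + [0.0] * 6)
        split = split_by_median(table, "content")
        counts = np.array([2] * 6 + [1] * 6)
        res = breakpoint_fold_and_test(counts, split)
        assert res.fold == pytest.approx(2.0)

    def test_zero_below_mean_flags_infinite(self):
        table = window_table([1.0] * 3 + [0.0] * 3)
        split = split_by_median(table, "content")
        res = breakpoint_fold_and_test(np.array([2, 2, 2, 0, 0, 0]), split)
        assert res.infinite_fold and np.isinf(res.fold)

    def test_null_distribution_rarely_rejects(self):
        """Identical count distributions in the two strata: fold near 1,
        p > 0.05 in >= 90% of seeds."""
        ok_p, folds = 0, []
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            contents = r.normal(size=200)
            counts = r.poisson(3.0, size=200)
            split = split_by_median(window_table(list(contents)), "content")
            res = breakpoint_fold_and_test(counts, split)
            ok_p += res.p_value > 0.05
            folds.append(res.fold)
        assert ok_p / n_seeds >= 0.90
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    def test_planted_coupling_detected(self):
        """Breakpoints concentrated in element-rich windows: fold > 1 and
        p < 0.01 at n = 1000 windows."""
        r = np.random.default_rng(11)
        contents = r.normal(size=1000)
        rich = contents > np.median(contents)
        counts = r.poisson(np.where(rich, 4.0, 2.0))
        split = split_by_median(window_table(list(contents)), "content")
        res = breakpoint_fold_and_test(counts, split)
        assert res.fold > 1.5
        assert res.p_value < 0.01


class TestFisher:
    def test_no_association_table(self):
        p, odds = fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_diagonal_table_enumeration_value(self):
        # margins (2,2)/(2,2): tables (0..2 in cell a), masses 1/6, 4/6, 1/6
        p, _ = fisher_exact_two_sided(ContingencyTable2x2(2, 0, 0, 2))
        assert p == pytest.approx(1 / 3)
        assert p == pytest.approx(fisher_enumeration_oracle(2, 0, 0, 2))

    def test_symmetry_under_row_and_column_swaps(self):
        base = ContingencyTable2x2(7, 2, 3, 8)
        p0, _ = fisher_exact_two_sided(base)
        for t in (ContingencyTable2x2(3, 8, 7, 2),
                  ContingencyTable2x2(2, 7, 8, 3),
                  ContingencyTable2x2(8, 3, 2, 7)):
            p, _ = fisher_exact_two_sided(t)
            assert p == pytest.approx(p0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestRegionEnrichment:
    def test_identical_regions_give_no_association(self):
        table = window_table(list(np.arange(20, dtype=float)))
        region = np.zeros(20, dtype=bool)
        region[:10] = True
        ct, p, odds = region_element_enrichment(table, "content",
                                                region, region)
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_planted_enrichment_detected(self, rng):
        n = 400
        contents = rng.normal(size=n)
        region_a = np.zeros(n, dtype=bool)
        region_a[:100] = True
        contents[:100] += 2.0  # region A pushed above the global median
        table = window_table(list(contents))
        ct, p, _ = region_element_enrichment(table, "content", region_a,
                                             ~region_a)
        assert p < 0.01
        assert ct.a / (ct.a + ct.b) > ct.c / (ct.c + ct.d)

    def test_median_split_fisher_calibration(self):
        """Exchangeable windows, Table-1-like margins (region of 125 vs
        574): the Fisher p-value CDF stays inside the two-sided KS band
        at alpha = 0.01 and the 5% rejection rate is honest."""
        r = np.random.default_rng(2023)
        n, n_region = 699, 125
        ps = []
        for _ in range(200):
            contents = r.normal(size=n)
            region = np.zeros(n, dtype=bool)
            region[r.permutation(n)[:n_region]] = True
            table = window_table(list(contents))
            _, p, _ = region_element_enrichment(table, "content", region,
                                                ~region)
            ps.append(p)
        ps = np.array(ps)
        d = sps.kstest(ps, "uniform").statistic
        assert d < sps.kstwobign.ppf(0.99) / np.sqrt(len(ps))
        assert 0.01 <= (ps <= 0.05).mean() <= 0.09


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 extreme of 20 assignments

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_n(self, seed):
        r = np.random.default_rng(seed)
        xs = r.integers(0, 6, size=5).astype(float)
        ys = r.integers(0, 6, size=6).astype(float)
        u, p = mann_whitney(xs, ys)
        u_oracle, p_oracle = mw_enumeration_oracle(xs, ys)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle)

    def test_large_sample_calibration(self):
        """Same-distribution Gaussians, n = m = 50: rejection rate at
        alpha = 0.05 within [0.03, 0.07] over 1000 seeds."""
        rejections = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            r = np.random.default_rng(50_000 + seed)
            _, p = mann_whitney(r.normal(size=50), r.normal(size=50))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_seeds <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
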