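"""Chiasma scoring and the distributional statistics around it."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meiocross.chiasma import (
    BivalentRecord,
    cell_chiasma_frequency,
    cell_summaries_from_table,
    chiasmata_from_shape,
    class1_fraction,
    fold_change,
    poisson_gof,
    pooled_t_test,
    retention_percent,
    summarize_genotype,
)
from meiocross.simulate import genotype_config, simulate_dataset


class TestScoring:
    @pytest.mark.parametrize("shape,score", [("univalent_pair", 0), ("rod", 1), ("ring", 2)])
    def test_shape_to_chiasma_score(self, shape, score):
        assert chiasmata_from_shape(shape) == score

    def test_unknown_shape_label_rejected(self):
        with pytest.raises(ValueError, match="unknown shape"):
            chiasmata_from_shape("banana")

    def test_two_rods_ten_rings_score_22(self):
        records = [BivalentRecord("c1", "rod")] * 2 + [BivalentRecord("c1", "ring")] * 10
        s = cell_chiasma_frequency(records)
        assert (s.chiasma_count, s.bivalent_count) == (22, 12)

    def test_all_univalents_score_zero(self):
        records = [BivalentRecord("c1", "univalent_pair")] * 12
        s = cell_chiasma_frequency(records)
        assert (s.chiasma_count, s.bivalent_count) == (0, 0)

    def test_univalent_pairs_not_counted_as_bivalents(self):
        # a cell with five ring bivalents and fourteen univalents
        records = [BivalentRecord("c1", "ring")] * 5 + [BivalentRecord("c1", "univalent_pair")] * 7
        assert cell_chiasma_frequency(records).bivalent_count == 5

    def test_empty_and_mixed_cells_rejected(self):
        with pytest.raises(ValueError):
            cell_chiasma_frequency([])
        with pytest.raises(ValueError, match="multiple cells"):
            cell_chiasma_frequency([BivalentRecord("c1", "rod"), BivalentRecord("c2", "rod")])

    def test_table_aggregation_conserves_total_score(self):
        """Sum of per-cell chiasma counts equals the sum of per-bivalent
        scores over the whole dataset."""
        cells, _ = simulate_dataset(genotype_config("WT", n_cells=30, seed=9))
        per_cell = cell_summaries_from_table(cells)
        per_record = cells["shape_class"].map(chiasmata_from_shape).sum()
        assert per_cell["chiasma_count"].sum() == per_record


class TestSummaries:
    def test_constant_counts(self):
        assert summarize_genotype([1, 1, 1]) == (1.0, 0.0, 3)

    def test_hand_arithmetic(self):
        mean, sd, n = summarize_genotype([0, 2])
        assert (mean, n) == (1.0, 2)
        assert sd == pytest.approx(np.sqrt(2))

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            summarize_genotype([5])

    def test_recovers_residual_chiasma_mean(self):
        """hei10-like simulation recovers the ~6.5/cell residual mean."""
        cells, _ = simulate_dataset(genotype_config("hei10", n_cells=400, seed=17))
        mean, sd, n = summarize_genotype(cell_summaries_from_table(cells)["chiasma_count"])
        se = sd / np.sqrt(n)
        # scoring caps bivalents at two chiasmata, trimming the raw 6.5 rate slightly
        assert abs(mean - 6.26) < 3 * se


class TestPoissonGof:
    def test_nominal_type1_error_at_cytological_sample_size(self, rng):
        """Under a true Poisson null the rejection rate stays near alpha."""
        reps, rej = 300, 0
        for _ in range(reps):
            counts = rng.poisson(6.5, 130)
            rej += poisson_gof(counts.tolist()).p_value < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_large_sample_from_poisson_not_rejected(self, rng):
        """The typical large-sample Poisson draw is accepted: the median
        p-value over replicates is far above the 0.05 level (any single
        draw rejects with probability alpha by construction)."""
        pvals = [poisson_gof(rng.poisson(6.5, 10_000).tolist()).p_value for _ in range(11)]
        assert np.median(pvals) > 0.05

    def test_underdispersed_counts_rejected(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            res = poisson_gof([7] * 200)
        assert res.chi2 > 50 and res.p_value < 0.01

    def test_pooling_respects_min_expected(self, rng):
        counts = rng.poisson(6.5, 130)
        res = poisson_gof(counts.tolist(), min_expected=5)
        lam = np.mean(counts)
        edges = res.bin_edges
        n = len(counts)
        # every interior category must carry expected mass >= 5
        for lo, hi in zip(edges, edges[1:]):
            expected = n * (stats.poisson.cdf(hi - 1, lam) - stats.poisson.cdf(lo - 1, lam))
            assert expected >= 5 - 1e-9
        assert res.df == len(edges) - 2

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_gof([0, 0, 0, 0])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_gof([1.5, 2.5, 3.0])


class TestPooledT:
    def test_reproduces_mutant_comparison(self):
        """hei10 (6.5+/-2.1, n=130) vs mer3hei10 (2.1+/-1.3, n=121)."""
        res = pooled_t_test(6.5, 2.1, 130, 2.1, 1.3, 121)
        assert res.df == 249
        # 19.786 exactly from the rounded summaries; ~19.9 as published
        assert res.t == pytest.approx(19.786, abs=0.01)
        assert res.t == pytest.approx(19.9, abs=0.15)
        assert res.p_value < 0.01

    def test_identical_samples_give_zero(self):
        res = pooled_t_test(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0.0 and res.p_value == 1.0

    def test_matches_scipy_from_stats(self):
        mine = pooled_t_test(20.7, 1.4, 130, 6.5, 2.1, 130)
        ref = stats.ttest_ind_from_stats(20.7, 1.4, 130, 6.5, 2.1, 130, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_raw_sample_computation_to_1e10(self, rng):
        """Summary-statistic t equals scipy's raw-data t on samples built
        to have exactly the summarised moments."""
        def sample_with_moments(mean, sd, n):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = sample_with_moments(6.5, 2.1, 130)
        b = sample_with_moments(2.1, 1.3, 121)
        ref = stats.ttest_ind(a, b, equal_var=True)
        mine = pooled_t_test(6.5, 2.1, 130, 2.1, 1.3, 121)
        assert abs(mine.t - ref.statistic) < 1e-10
        assert abs(mine.p_value - ref.pvalue) < 1e-10

    def test_degenerate_zero_variance_equal_means(self):
        with pytest.raises(ZeroDivisionError):
            pooled_t_test(3.0, 0.0, 5, 3.0, 0.0, 5)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(1, 1, 1, 2, 1, 10)


class TestRatios:
    def test_chiasma_retention_values(self):
        assert retention_percent(6.5, 20.7) == pytest.approx(31.4, abs=0.05)
        assert retention_percent(5.8, 20.7) == pytest.approx(28.0, abs=0.05)
        assert retention_percent(7.0, 7.0) == 100.0

    def test_class1_pathway_fraction(self):
        assert class1_fraction(24.3, 28.3) == pytest.approx(85.9, abs=0.05)
        assert class1_fraction(0.0, 10.0) == 0.0

    def test_focus_fold_change(self):
        assert fold_change(36.2, 24.5) == pytest.approx(1.48, abs=0.005)
        assert round(fold_change(36.2, 24.5), 1) == 1.5

    @given(
        num=st.floats(0.1, 1e3),
        den=st.floats(0.1, 1e3),
        c=st.floats(0.01, 1e3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_ratios_scale_invariant(self, num, den, c):
        assert retention_percent(num * c, den * c) == pytest.approx(retention_percent(num, den), rel=1e-9)
        assert class1_fraction(num * c, den * c) == pytest.approx(class1_fraction(num, den), rel=1e-9)

    def test_invalid_denominators(self):
        with pytest.raises(ValueError):
            retention_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            class1_fraction(1.0, -2.0)
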