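"""Equal-count binning, distribution tables, slopes and their tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slfomap as sm
from slfomap.distribution import _two_sample_t
from slfomap.exceptions import InsufficientVoxelsError, ParameterError
from slfomap.types import TissueMasks


def make_bins(values, valid=None, n_bins=10, shape=None):
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (values.size, 1, 1)
    vol = values.reshape(shape, order="F")
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return sm.rank_and_bin(vol, valid, n_bins=n_bins)


class TestRankAndBin:
    def test_exact_deciles(self):
        bins = make_bins(np.arange(1, 101))
        idx = bins.bin_index.ravel(order="F")
        assert (idx[:10] == 1).all() and (idx[90:] == 10).all()
        assert (bins.bin_counts() == 10).all()

    def test_remainder_goes_to_lowest_bins(self):
        bins = make_bins(np.arange(103))
        assert list(bins.bin_counts()) == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_all_ties_stable_by_voxel_index(self):
        bins = make_bins(np.zeros(40), n_bins=4)
        idx = bins.bin_index.ravel(order="F")
        # stable sort on constant values orders by x-fastest linear index
        assert (idx == np.repeat([1, 2, 3, 4], 10)).all()

    def test_values_nondecreasing_with_bin(self, rng):
        vals = rng.standard_normal(250)
        bins = make_bins(vals)
        idx = bins.bin_index.ravel(order="F")
        means = [vals[idx == b].max() for b in range(1, 10)]
        nxt = [vals[idx == b].min() for b in range(2, 11)]
        assert all(m <= n for m, n in zip(means, nxt))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rank_invariance_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        vals = r.standard_normal(137)
        b1 = make_bins(vals)
        b2 = make_bins(np.exp(2.0 * vals) + 5.0)
        np.testing.assert_array_equal(b1.bin_index, b2.bin_index)

    def test_too_few_valid_rejected(self):
        with pytest.raises(InsufficientVoxelsError):
            make_bins(np.arange(5))


def toy_masks():
    """20 voxels in a line: 10 GM then 10 WM; all brain."""
    shape = (20, 1, 1)
    gm = np.zeros(shape, bool)
    wm = np.zeros(shape, bool)
    gm[:10] = True
    wm[10:] = True
    z = np.zeros(shape, bool)
    return TissueMasks(wm=wm, gm=gm, csf=z.copy(), va=z.copy(),
                       brain=np.ones(shape, bool), sss=z.copy())


class TestTissueFractions:
    def test_containment_and_counts(self):
        masks = toy_masks()
        # ascending values 0..19: bin1 = first 10 voxels = all GM
        bins = make_bins(np.arange(20), n_bins=2, shape=(20, 1, 1))
        table = sm.bin_tissue_fractions(bins, masks)
        np.testing.assert_allclose(table.fractions[0], [1, 0, 0, 0, 0])
        np.testing.assert_allclose(table.fractions[1], [0, 1, 0, 0, 0])

    def test_mixed_bin_direct_count(self):
        masks = toy_masks()
        vals = np.arange(20)
        vals[5:10] = 100 + np.arange(5)  # push 5 GM voxels into the top bin
        bins = make_bins(vals, n_bins=2, shape=(20, 1, 1))
        table = sm.bin_tissue_fractions(bins, masks)
        np.testing.assert_allclose(table.fractions[1], [0.5, 0.5, 0, 0, 0])

    def test_rows_sum_to_one(self, small_cohort):
        series, masks, _ = small_cohort[0]
        res = sm.run_subject(series, masks, preprocessed=True)
        for table in (res.table_maxcc, res.table_alff):
            np.testing.assert_allclose(table.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_va_enriched_in_top_bin(self, small_cohort):
        """VA has the largest planted mixing fraction, so its share of the
        top maxcc decile exceeds its share of the bottom one."""
        series, masks, _ = small_cohort[0]
        res = sm.run_subject(series, masks, preprocessed=True)
        va = res.table_maxcc.curve("VA")
        assert va[-1] > va[0]


class TestSlopes:
    def test_exact_line(self):
        table = sm.DistributionTable(
            fractions=np.column_stack([np.linspace(0.1, 1.0, 10)] + [np.zeros(10)] * 4)
        )
        est = sm.fit_distribution_slope(table, "GM")
        assert abs(est.slope - 0.1) < 1e-12
        assert est.stderr < 1e-12

    def test_flat_line(self):
        table = sm.DistributionTable(fractions=np.full((10, 5), 0.2))
        assert abs(sm.fit_distribution_slope(table, "WM").slope) < 1e-15

    def test_matches_normal_equations_oracle(self, rng):
        y = 0.05 * np.arange(1, 11) + rng.normal(0, 0.01, 10)
        table = sm.DistributionTable(
            fractions=np.column_stack([y] + [np.zeros(10)] * 4)
        )
        est = sm.fit_distribution_slope(table, "GM")
        x = np.arange(1, 11, dtype=float)
        n = 10
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        intercept = y.mean() - slope * x.mean()
        assert abs(est.slope - slope) < 1e-12
        assert abs(est.intercept - intercept) < 1e-12


class TestGroupAveraging:
    def test_identical_tables(self):
        t = sm.DistributionTable(fractions=np.full((10, 5), 0.2))
        g = sm.average_distributions([t, t])
        np.testing.assert_allclose(g.mean_fractions, 0.2)
        np.testing.assert_allclose(g.sd_fractions, 0.0)

    def test_two_point_mean(self):
        a = sm.DistributionTable(fractions=np.zeros((4, 5)))
        f = np.zeros((4, 5))
        f[:, 0] = 1.0
        b = sm.DistributionTable(fractions=f)
        g = sm.average_distributions([a, b])
        assert g.mean_fractions[0, 0] == 0.5
        np.testing.assert_allclose(g.sd_fractions[:, 0], np.sqrt(0.5))

    def test_single_table_rejected(self):
        t = sm.DistributionTable(fractions=np.full((10, 5), 0.2))
        with pytest.raises(ParameterError):
            sm.average_distributions([t])


class TestSlopeTests:
    def test_all_zero_slopes(self):
        r = sm.test_slope_nonzero([0.0, 0.0, 0.0, 0.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_identical_nonzero_slopes_degenerate(self):
        r = sm.test_slope_nonzero([0.1, 0.1, 0.1, 0.1])
        assert r.p == 0.0 and r.degenerate

    def test_two_sample_identical_lists(self):
        r = sm.compare_slope_sets([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert r.t == 0.0 and r.p == 1.0

    def test_two_sample_large_separation(self, rng):
        a = [0.0, 0.0, 0.0, 0.0]
        b = 1.0 + rng.normal(0, 0.01, 4)
        r = sm.compare_slope_sets(a, list(b))
        assert r.p < 1e-6

    def test_two_sample_matches_closed_form(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 6)
        got = _two_sample_t(x, y)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert abs(got.t - t) < 1e-12


class TestCompareBins:
    def _tables(self, vals_a, vals_b, bin_a=10, bin_b=9):
        tables = []
        for va, vb in zip(vals_a, vals_b):
            f = np.full((10, 5), 0.1)
            f[bin_a - 1, 0] = va
            f[bin_b - 1, 0] = vb
            tables.append(sm.DistributionTable(fractions=f))
        return tables

    def test_identical_bins(self):
        tables = self._tables([0.2, 0.3, 0.25], [0.2, 0.3, 0.25])
        r = sm.compare_bins(tables, "GM", 10, 9)
        assert r.p == 1.0

    def test_ten_sd_separation_significant(self, rng):
        base = rng.normal(0.2, 0.01, 8)
        tables = self._tables(base + 0.1, base)  # 10x the sd apart
        r = sm.compare_bins(tables, "GM", 10, 9)
        assert r.p < 0.001

    def test_bin_out_of_range_rejected(self):
        tables = self._tables([0.2, 0.2], [0.2, 0.2])
        with pytest.raises(ParameterError):
            sm.compare_bins(tables, "GM", 11, 9)


class TestCurveCorrelation:
    def test_identical_curves(self):
        t = sm.DistributionTable(
            fractions=np.column_stack([np.linspace(0, 1, 10)] + [np.zeros(10)] * 4)
        )
        assert abs(sm.curve_correlation(t, t, "GM") - 1.0) < 1e-12

    def test_negated_curve(self):
        y = np.linspace(0, 1, 10)
        a = sm.DistributionTable(fractions=np.column_stack([y] + [np.zeros(10)] * 4))
        b = sm.DistributionTable(
            fractions=np.column_stack([2 * y.mean() - y] + [np.zeros(10)] * 4)
        )
        assert abs(sm.curve_correlation(a, b, "GM") + 1.0) < 1e-12


class TestQuantileMasks:
    def test_partition_of_valid_mask(self, rng):
        vals = rng.standard_normal((10, 5, 4))
        valid = rng.random((10, 5, 4)) > 0.3
        bins = sm.rank_and_bin(vals, valid)
        masks = sm.export_quantile_masks(bins, group_size=2)
        assert len(masks) == 5
        union = np.zeros_like(valid)
        for i, m in enumerate(masks):
            for other in masks[i + 1:]:
                assert not (m & other).any()
            union |= m
        np.testing.assert_array_equal(union, valid)

    def test_indivisible_grouping_rejected(self, rng):
        vals = rng.standard_normal((10, 5, 4))
        bins = sm.rank_and_bin(vals, np.ones((10, 5, 4), bool))
        with pytest.raises(ParameterError):
            sm.export_quantile_masks(bins, group_size=3)
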