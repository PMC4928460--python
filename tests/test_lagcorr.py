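"""Lagged cross-correlation mapping against a first-principles oracle."""

import numpy as np
import pytest

import slfomap as sm
from slfomap.exceptions import InvalidLengthError, SamplingError, ShapeError
from slfomap.lagcorr import lagged_pearson, max_correlation
from slfomap.types import BoldSeries4D, SeedTimecourse


from oracles import oracle_best, oracle_lagged


class TestLaggedPearson:
    def test_self_correlation_peaks_at_zero_lag(self, rng):
        x = rng.standard_normal(200)
        maxcc, lag = max_correlation(lagged_pearson(x, x, 0.72))
        assert lag == 0.0
        assert abs(maxcc - 1.0) < 1e-12

    def test_circular_shift_recovered_exactly(self, rng):
        """A +3 TR circular shift of a periodic construction gives r = 1 at
        lag 3*tr: wrap the sequence so the overlap is exact."""
        base = rng.standard_normal(200)
        voxel = np.roll(base, 3)
        pairs = lagged_pearson(base, voxel, 0.72, lag_limit_s=6.0)
        # restrict to the non-wrapped comparison: the exact-match lag exists
        best = max(pairs, key=lambda p: p.r)
        assert abs(best.lag_s - 3 * 0.72) < 1e-12
        assert best.r > 0.999  # wrapped samples only affect other lags

    def test_matches_brute_force_oracle(self, rng):
        seed = rng.standard_normal(200)
        voxel = rng.standard_normal(200)
        got = lagged_pearson(seed, voxel, 0.72, lag_limit_s=8 * 0.72)
        want = oracle_lagged(seed, voxel, 0.72, 8 * 0.72)
        assert len(got) == len(want) == 17
        for (lg, rg, _), (lw, rw) in zip(got, want):
            assert abs(lg - lw) < 1e-12
            assert abs(rg - rw) < 1e-10

    def test_zero_variance_overlap_flagged(self):
        seed = np.sin(np.arange(100))
        voxel = np.zeros(100)
        pairs = lagged_pearson(seed, voxel, 0.72)
        assert all(p.r == 0.0 and p.degenerate for p in pairs)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            lagged_pearson(rng.standard_normal(100), rng.standard_normal(99), 0.72)

    def test_symmetry_swapping_negates_lag(self, rng):
        """With an exact circular-shift pair the optimal lag negates when
        seed and voxel swap roles; maxcc is unchanged."""
        base = rng.standard_normal(300)
        voxel = np.roll(base, 2)
        m1, l1 = max_correlation(lagged_pearson(base, voxel, 0.72))
        m2, l2 = max_correlation(lagged_pearson(voxel, base, 0.72))
        assert abs(l1 + l2) < 1e-10
        assert abs(m1 - m2) < 1e-10


class TestMaxCorrelation:
    @pytest.mark.parametrize(
        "pairs, expect",
        [
            ([(-0.72, 0.2), (0.0, 0.5), (0.72, 0.4)], (0.5, 0.0)),
            ([(-0.72, 0.5), (0.72, 0.5)], (0.5, -0.72)),  # negative lag wins ties
            ([(-1.44, 0.5), (0.72, 0.5)], (0.5, 0.72)),  # smaller |lag| first
        ],
    )
    def test_maximum_and_tie_breaks(self, pairs, expect):
        assert max_correlation(pairs) == expect

    def test_empty_rejected(self):
        with pytest.raises(sm.exceptions.EmptyRoiError):
            max_correlation([])


class TestMaxccMap:
    def test_map_equals_per_voxel_brute_force(self):
        """Vectorized map vs naive triple loop on a 6x6x4x200 phantom."""
        spec = sm.PhantomSpec(grid_shape=(6, 6, 4), n_timepoints=200, rng_seed=17)
        series, masks, _ = sm.generate_phantom(spec)
        seed = sm.extract_seed(series, masks.sss)
        lag_map = sm.compute_maxcc_map(series, seed, masks.brain)
        for idx in np.argwhere(masks.brain):
            idx = tuple(idx)
            pairs = oracle_lagged(
                seed.values, series.data[idx], spec.tr_seconds, 6.0
            )
            lag_w, r_w = oracle_best(pairs)
            assert abs(lag_map.maxcc[idx] - r_w) < 1e-10
            assert abs(lag_map.lag_s[idx] - lag_w) < 1e-10

    def test_noise_free_exact_recovery(self, clean_phantom):
        """No noise, no cardiac: every voxel with planted signal is valid
        with maxcc 1 at exactly the planted lag."""
        series, masks, truth = clean_phantom
        seed = sm.extract_seed(series, masks.sss)
        m = sm.compute_maxcc_map(series, seed, masks.brain)
        sel = masks.brain & (truth.true_mixing_fraction > 0)
        assert m.valid[sel].all()
        np.testing.assert_allclose(m.maxcc[sel], 1.0, atol=1e-9)
        np.testing.assert_allclose(m.lag_s[sel], truth.true_lag_s[sel], atol=1e-12)

    def test_pure_noise_valid_fraction_small(self):
        """No planted signal: the max-over-lags null rarely exceeds 0.3."""
        spec = sm.PhantomSpec(
            grid_shape=(16, 16, 8),
            mixing_fraction_by_tissue={"VA": 0, "GM": 0, "WM": 0, "CSF": 0},
            cardiac_amplitude_arterial=0.0,
            noise_sd=1.0,
            rng_seed=5,
        )
        series, masks, _ = sm.generate_phantom(spec)
        seed = sm.extract_seed(series, masks.sss)
        m = sm.compute_maxcc_map(series, seed, masks.brain)
        # the seed ROI voxels correlate with their own mean; exclude them
        valid_outside = m.valid & ~masks.sss
        assert valid_outside.sum() / masks.brain.sum() < 0.02

    def test_threshold_is_strict(self, rng):
        data = rng.standard_normal((2, 1, 1, 120))
        series = BoldSeries4D(data=data, tr_seconds=0.72)
        seed = SeedTimecourse(values=data[0, 0, 0], tr_seconds=0.72)
        brain = np.ones((2, 1, 1), dtype=bool)
        m = sm.compute_maxcc_map(series, seed, brain)
        # a voxel at exactly its own maxcc threshold must be invalid
        mc = m.maxcc[1, 0, 0]
        m2 = sm.compute_maxcc_map(series, seed, brain, threshold=float(mc))
        assert not m2.valid[1, 0, 0]
        assert m2.valid[0, 0, 0]  # r = 1 > any threshold below 1

    def test_maxcc_monotone_in_mixing_fraction(self):
        """Holding noise fixed, tissue-mean maxcc follows the planted mixing
        fraction ordering WM < GM < VA."""
        spec = sm.PhantomSpec(grid_shape=(16, 16, 8), rng_seed=31)
        series, masks, truth = sm.generate_phantom(spec)
        seed = sm.extract_seed(series, masks.sss)
        m = sm.compute_maxcc_map(series, seed, masks.brain)
        zone = sm.arterial_zone(spec.grid_shape)
        means = []
        for mask in (masks.wm, masks.gm, masks.va):
            sel = mask & ~zone
            assert sel.sum() >= 30 or mask is masks.va
            means.append(np.nanmean(m.maxcc[sel]))
        assert means[0] < means[1] < means[2]

    def test_outside_brain_is_invalid_nan(self, small_phantom):
        series, masks, _ = small_phantom
        seed = sm.extract_seed(series, masks.sss)
        m = sm.compute_maxcc_map(series, seed, masks.brain)
        assert not m.valid[~masks.brain].any()
        assert np.isnan(m.maxcc[~masks.brain]).all()

    def test_tr_mismatch_rejected(self, small_phantom, rng):
        series, masks, _ = small_phantom
        seed = SeedTimecourse(
            values=rng.standard_normal(series.n_timepoints), tr_seconds=1.0
        )
        with pytest.raises(SamplingError):
            sm.compute_maxcc_map(series, seed, masks.brain)

    def test_seed_length_mismatch_rejected(self, small_phantom, rng):
        series, masks, _ = small_phantom
        seed = SeedTimecourse(values=rng.standard_normal(33), tr_seconds=0.72)
        with pytest.raises(ShapeError):
            sm.compute_maxcc_map(series, seed, masks.brain)

    def test_short_series_rejected(self, rng):
        data = rng.standard_normal((2, 1, 1, 15))
        series = BoldSeries4D(data=data, tr_seconds=0.72)
        seed = SeedTimecourse(values=data[0, 0, 0], tr_seconds=0.72)
        with pytest.raises(InvalidLengthError):
            sm.compute_maxcc_map(series, seed, np.ones((2, 1, 1), dtype=bool))
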