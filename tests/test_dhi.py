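"""DHI computation: composites, the three bands, and a brute-force oracle."""

import numpy as np
import pytest

from moosehab.dhi import (CompositeSeries, FparStack, composite_fpar, compute_dhi,
                          cumulative_dhi, default_winter_periods, minimum_dhi,
                          variation_dhi)


def _stack(values, period_days=8):
    return FparStack(np.asarray(values, dtype=float), period_length_days=period_days)


def _series(values):
    v = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return CompositeSeries(v, 16)


class TestComposite:
    def test_median_across_years(self):
        # one pixel, one period, two years: median of {0.4, 0.6} is 0.5
        st = _stack(np.array([0.4, 0.6]).reshape(2, 1, 1, 1))
        assert composite_fpar(st).values[0, 0, 0] == pytest.approx(0.5)
        st3 = _stack(np.array([0.2, 0.5, 0.9]).reshape(3, 1, 1, 1))
        assert composite_fpar(st3).values[0, 0, 0] == pytest.approx(0.5)

    def test_missing_years_are_skipped(self):
        st = _stack(np.array([0.4, np.nan]).reshape(2, 1, 1, 1))
        assert composite_fpar(st).values[0, 0, 0] == pytest.approx(0.4)
        st_all = _stack(np.array([np.nan, np.nan]).reshape(2, 1, 1, 1))
        assert np.isnan(composite_fpar(st_all).values[0, 0, 0])

    def test_16_day_aggregation_pools_period_pairs(self):
        # 2 years x 4 periods; 8->16 day pools pairs with the years
        vals = np.array([[0.1, 0.3, 0.5, 0.7], [0.2, 0.4, 0.6, 0.8]]).reshape(2, 4, 1, 1)
        comp = composite_fpar(_stack(vals), target_period_days=16)
        assert comp.values.shape[0] == 2
        assert comp.values[0, 0, 0] == pytest.approx(np.median([0.1, 0.3, 0.2, 0.4]))
        assert comp.values[1, 0, 0] == pytest.approx(np.median([0.5, 0.7, 0.6, 0.8]))

    def test_incompatible_period_length_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            composite_fpar(_stack(np.full((1, 4, 1, 1), 0.5)), target_period_days=12)

    def test_year_order_invariance(self, rng):
        vals = rng.uniform(0, 1, size=(5, 8, 3, 3))
        st = _stack(vals)
        perm = _stack(vals[rng.permutation(5)])
        np.testing.assert_array_equal(composite_fpar(st).values, composite_fpar(perm).values)


class TestBands:
    def test_cumulative_sums_available_periods(self):
        assert cumulative_dhi(_series([0.1, 0.2, 0.3]))[0, 0] == pytest.approx(0.6)
        assert cumulative_dhi(_series([0.0] * 7))[0, 0] == 0.0
        assert cumulative_dhi(_series([0.5] * 46))[0, 0] == pytest.approx(23.0)
        assert cumulative_dhi(_series([0.1, np.nan, 0.3]))[0, 0] == pytest.approx(0.4)

    def test_minimum_and_darkness_fill(self):
        assert minimum_dhi(_series([0.3, 0.1, 0.5]), darkness_fill=False)[0, 0] == pytest.approx(0.1)
        assert minimum_dhi(_series([0.7] * 5))[0, 0] == pytest.approx(0.7)
        # winter gap: missing first period -> productivity floor set to zero
        gap = _series([np.nan, 0.4, 0.6, 0.5, 0.3, 0.2, 0.3, 0.5])
        assert minimum_dhi(gap, darkness_fill=True)[0, 0] == 0.0
        assert minimum_dhi(gap, darkness_fill=False)[0, 0] == pytest.approx(0.2)

    def test_variation_is_sample_cv(self):
        # sd of {0.1,0.2,0.3} with n-1 denominator is 0.1; mean 0.2 -> CV 0.5
        assert variation_dhi(_series([0.1, 0.2, 0.3]))[0, 0] == pytest.approx(0.5)
        assert variation_dhi(_series([0.4] * 6))[0, 0] == pytest.approx(0.0)

    def test_variation_scale_invariance(self, rng):
        base = rng.uniform(0.1, 0.5, size=8)
        a = variation_dhi(_series(base))[0, 0]
        b = variation_dhi(_series(1.9 * base))[0, 0]
        assert a == pytest.approx(b)

    def test_zero_mean_pixel_is_missing(self):
        assert np.isnan(variation_dhi(_series([0.0, 0.0, 0.0]))[0, 0])

    def test_winter_periods_cover_year_edges(self):
        w = default_winter_periods(46)
        assert set(w) == set(range(6)) | set(range(40, 46))


class TestComputeDhi:
    def test_sinusoid_matches_closed_form(self):
        # noiseless seasonal pixel repeated over years: composite equals the
        # sampled sinusoid, so the bands equal its sum, min and sample CV
        pp, m, a = 12, 0.5, 0.3
        season = m + a * -np.cos(2 * np.pi * (np.arange(pp) + 0.5) / pp)
        vals = np.tile(season.reshape(1, pp, 1, 1), (3, 1, 1, 1))
        dhi = compute_dhi(FparStack(vals), target_period_days=8, darkness_fill=False)
        assert dhi.cumulative[0, 0] == pytest.approx(season.sum())
        assert dhi.minimum[0, 0] == pytest.approx(season.min())
        assert dhi.variation[0, 0] == pytest.approx(season.std(ddof=1) / season.mean())

    def test_scaled_pixels_share_variation(self, rng):
        base = rng.uniform(0.05, 0.45, size=(2, 4, 1, 1))
        vals = np.concatenate([base, 2 * base], axis=3)
        dhi = compute_dhi(FparStack(vals), target_period_days=8, darkness_fill=False)
        assert dhi.variation[0, 0] == pytest.approx(dhi.variation[0, 1])

    def test_all_missing_pixel_missing_everywhere(self):
        vals = np.full((2, 4, 1, 2), 0.5)
        vals[:, :, 0, 1] = np.nan
        dhi = compute_dhi(FparStack(vals), target_period_days=8)
        assert np.isnan(dhi.cumulative[0, 1])
        assert np.isnan(dhi.minimum[0, 1])
        assert np.isnan(dhi.variation[0, 1])

    def test_minimum_never_exceeds_mean(self, rng):
        vals = rng.uniform(0, 1, size=(3, 8, 4, 4))
        dhi = compute_dhi(FparStack(vals), target_period_days=8, darkness_fill=False)
        mean = dhi.cumulative / 8
        assert np.all(dhi.minimum <= mean + 1e-12)
        assert np.all(dhi.variation >= 0)


def bruteforce_dhi(values, darkness_fill=True):
    """Independent nested-loop recomputation on an 8-day stack (no 16-day
    aggregation): per pixel, per period median across years, then sum /
    min (zero-filled on winter gaps) / sample CV over available periods."""
    ny, npd, h, w = values.shape
    winter = set(default_winter_periods(npd).tolist())
    cum = np.full((h, w), np.nan)
    mn = np.full((h, w), np.nan)
    var = np.full((h, w), np.nan)
    for i in range(h):
        for j in range(w):
            comp = []
            for p in range(npd):
                obs = [values[y, p, i, j] for y in range(ny)
                       if not np.isnan(values[y, p, i, j])]
                comp.append(np.median(obs) if obs else np.nan)
            avail = [c for c in comp if not np.isnan(c)]
            if not avail:
                continue
            cum[i, j] = sum(avail)
            mn[i, j] = min(avail)
            if darkness_fill and any(np.isnan(comp[p]) for p in winter):
                mn[i, j] = 0.0
            if len(avail) >= 2:
                mean = np.mean(avail)
                if mean > 0:
                    var[i, j] = np.std(avail, ddof=1) / mean
    return cum, mn, var


def test_matches_bruteforce_on_random_small_stacks(rng):
    for _ in range(10):
        vals = rng.uniform(0, 1, size=(2, 4, 3, 3))
        vals[rng.random(vals.shape) < 0.25] = np.nan
        dhi = compute_dhi(FparStack(vals), target_period_days=8)
        cum, mn, var = bruteforce_dhi(vals)
        np.testing.assert_allclose(dhi.cumulative, cum, equal_nan=True)
        np.testing.assert_allclose(dhi.minimum, mn, equal_nan=True)
        np.testing.assert_allclose(dhi.variation, var, equal_nan=True)
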