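"""Pixel-wise map statistics and gated scalar tests."""

import numpy as np
import pytest
from scipy import stats

from aortaflow import (
    ProjectionMap, GroupMapStack, pixelwise_compare, dispersion_summary,
    grubbs_outliers, scalar_test, correlate,
)


def _maps(rng, n_animals, shape=(50, 40), mean=0.0, sd=1.0):
    gz = np.arange(shape[0]) * 0.02
    gt = np.arange(shape[1]) * 9.0
    out = []
    for _ in range(n_animals):
        v = rng.normal(mean, sd, size=shape)
        out.append(ProjectionMap(gz, gt, v, np.ones(shape, bool)))
    return out


class TestPixelwiseCompare:
    def test_identical_constant_groups(self):
        gz, gt = np.arange(10) * 1.0, np.arange(8) * 1.0
        maps = [ProjectionMap(gz, gt, np.full((10, 8), 2.0),
                              np.ones((10, 8), bool)) for _ in range(3)]
        cm = pixelwise_compare(GroupMapStack("a", maps[:2] + [maps[2]]),
                               GroupMapStack("b", [m for m in maps]))
        np.testing.assert_allclose(cm.difference[cm.valid], 0.0, atol=1e-15)
        assert np.all(np.isnan(cm.p_map))  # zero variance -> undefined sentinel
        assert not cm.sig_mask.any()

    def test_extreme_effect_size_power(self):
        rng = np.random.default_rng(11)
        a = _maps(rng, 5, mean=1.0, sd=0.01)
        b = _maps(rng, 5, mean=0.0, sd=0.01)
        cm = pixelwise_compare(GroupMapStack("a", a), GroupMapStack("b", b))
        assert cm.sig_mask[cm.valid].mean() > 0.99
        np.testing.assert_allclose(cm.difference[cm.valid], 1.0, atol=0.05)

    def test_null_calibration(self):
        rng = np.random.default_rng(2024)
        a = _maps(rng, 5, shape=(100, 100))
        b = _maps(rng, 5, shape=(100, 100))
        cm = pixelwise_compare(GroupMapStack("a", a), GroupMapStack("b", b))
        frac = cm.sig_mask[cm.valid].mean()
        assert 0.04 <= frac <= 0.06

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        a = _maps(rng, 4)
        b = _maps(rng, 5)
        ab = pixelwise_compare(GroupMapStack("a", a), GroupMapStack("b", b))
        ba = pixelwise_compare(GroupMapStack("b", b), GroupMapStack("a", a))
        np.testing.assert_array_equal(ab.difference, -ba.difference)

    def test_validity_intersection(self):
        rng = np.random.default_rng(4)
        a = _maps(rng, 2)
        b = _maps(rng, 2)
        a[0].valid[3, :] = False
        b[1].valid[:, 5] = False
        cm = pixelwise_compare(GroupMapStack("a", a), GroupMapStack("b", b))
        assert not cm.valid[3, :].any()
        assert not cm.valid[:, 5].any()
        assert np.all(np.isnan(cm.p_map[3, :]))

    def test_small_group_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="2 animals"):
            pixelwise_compare(GroupMapStack("a", _maps(rng, 1)),
                              GroupMapStack("b", _maps(rng, 3)))

    def test_mann_whitney_option(self):
        rng = np.random.default_rng(6)
        a = _maps(rng, 5, mean=2.0)
        b = _maps(rng, 5, mean=0.0)
        cm = pixelwise_compare(GroupMapStack("a", a), GroupMapStack("b", b),
                               test="mann_whitney")
        assert cm.test == "mann_whitney"
        assert cm.sig_mask[cm.valid].mean() > 0.3


class TestDispersionSummary:
    def test_identical_maps_zero(self):
        rng = np.random.default_rng(0)
        m = _maps(rng, 1)[0]
        d = dispersion_summary(GroupMapStack("g", [m, m, m]))
        assert d.median_sd == d.lower_quartile_sd == d.upper_quartile_sd == 0.0

    def test_iid_noise_median_sd(self):
        # spatial median of per-pixel sample SDs at n=6 converges to
        # sigma * sqrt(chi2.median(5) / 5)
        rng = np.random.default_rng(77)
        sigma = 0.3
        maps = _maps(rng, 6, shape=(200, 200), sd=sigma)
        d = dispersion_summary(GroupMapStack("g", maps))
        expected = sigma * np.sqrt(stats.chi2.median(5) / 5)
        assert d.median_sd == pytest.approx(expected, rel=0.02)
        assert d.lower_quartile_sd <= d.median_sd <= d.upper_quartile_sd

    def test_single_outlier_pixel(self):
        gz, gt = np.arange(100) * 1.0, np.arange(100) * 1.0
        base = np.zeros((100, 100))
        maps = []
        for i in range(4):
            v = base.copy()
            v[0, 0] = i  # only one pixel varies
            maps.append(ProjectionMap(gz, gt, v, np.ones_like(base, bool)))
        d = dispersion_summary(GroupMapStack("g", maps))
        assert d.median_sd == 0.0 and d.upper_quartile_sd == 0.0

    def test_shift_and_scale(self):
        rng = np.random.default_rng(9)
        maps = _maps(rng, 5)
        d0 = dispersion_summary(GroupMapStack("g", maps))
        shifted = [ProjectionMap(m.grid_z, m.grid_theta, m.values + 10.0,
                                 m.valid) for m in maps]
        scaled = [ProjectionMap(m.grid_z, m.grid_theta, 3.0 * m.values,
                                m.valid) for m in maps]
        d_sh = dispersion_summary(GroupMapStack("g", shifted))
        d_sc = dispersion_summary(GroupMapStack("g", scaled))
        assert d_sh.median_sd == pytest.approx(d0.median_sd, rel=1e-12)
        assert d_sc.median_sd == pytest.approx(3.0 * d0.median_sd, rel=1e-12)


class TestGrubbs:
    def test_single_extreme_outlier_removed(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 15), [10.0]])
        kept, removed = grubbs_outliers(x)
        assert removed == [15]
        assert len(kept) == 15

    def test_clean_data_untouched(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 15)
        kept, removed = grubbs_outliers(x)
        assert removed == []
        np.testing.assert_array_equal(kept, x)

    def test_removal_cap(self):
        # three outliers on very different scales are removable one at a
        # time; the cap stops the iteration after two
        x = np.concatenate([np.linspace(-0.1, 0.1, 10), [5.0, 500.0, 50000.0]])
        kept, removed = grubbs_outliers(x, max_removals=2)
        assert len(removed) == 2
        assert 5.0 in kept and 50000.0 not in kept

    def test_critical_value_against_t_distribution(self):
        # closed-form Grubbs critical value at n=10, alpha=0.05 is ~2.290
        from aortaflow.group_stats import _grubbs_critical
        assert _grubbs_critical(10, 0.05) == pytest.approx(2.290, abs=0.005)


class TestScalarTest:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = scalar_test([g, list(g)])
        assert res.p >= 0.99

    def test_separated_normals_parametric(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 10)
        b = rng.normal(3, 1, 10)
        res = scalar_test([a, b])
        assert res.test == "unpaired_t"
        assert res.normal
        assert res.p < 1e-3

    def test_nonnormal_routes_nonparametric(self):
        rng = np.random.default_rng(13)
        a = rng.lognormal(0, 2.0, 25)
        b = rng.lognormal(0.1, 2.0, 25)
        res = scalar_test([a, b])
        assert res.test == "mann_whitney"

    def test_multi_group_anova(self):
        rng = np.random.default_rng(14)
        gs = [rng.normal(m, 1, 10) for m in (0, 0.2, 5)]
        res = scalar_test(gs)
        assert res.test == "anova"
        assert res.p < 1e-6

    def test_small_group_falls_back(self):
        res = scalar_test([[1.0, 2.0], [5.0, 6.0]])
        assert res.test == "mann_whitney"

    def test_branch_choice_reproducible(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        r1 = scalar_test([a, b])
        r2 = scalar_test([a, b])
        assert (r1.test, r1.statistic, r1.p) == (r2.test, r2.statistic, r2.p)

    def test_outlier_excluded_before_test(self):
        rng = np.random.default_rng(16)
        a = np.concatenate([rng.normal(0, 1, 10), [30.0]])
        b = rng.normal(0, 1, 10)
        res = scalar_test([a, b])
        assert res.removed_outliers == [(0, 10)]


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-9

    def test_near_perfect_negative(self):
        rng = np.random.default_rng(17)
        x = np.arange(20.0)
        r, _ = correlate(x, -x + rng.normal(0, 1e-6, 20))
        assert r == pytest.approx(-1.0, abs=1e-4)

    def test_critical_value_calibration(self):
        # for independent N(0,1) pairs at n=20, |r| < 0.444 in ~95% of runs
        rng = np.random.default_rng(18)
        crit = stats.t.ppf(0.975, 18) / np.sqrt(18 + stats.t.ppf(0.975, 18) ** 2)
        assert crit == pytest.approx(0.444, abs=0.001)
        inside = 0
        for _ in range(1000):
            r, _ = correlate(rng.normal(size=20), rng.normal(size=20))
            inside += abs(r) < crit
        assert 0.93 <= inside / 1000 <= 0.97

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        r, _ = correlate(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
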