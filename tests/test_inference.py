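import numpy as np
import pandas as pd
import pytest

from paleosn import (DiversityCurve, AreaCurve, SNRateCurve,
                     normalize_diversity, pearson_with_ci, mc_correlation,
                     grid_scan, regional_convergence, exp_memory_forcing,
                     ConfigurationError)
from paleosn.inference import effective_n_ar1


def div_curve(ages, mean, sd=None, region="global", method="sqs"):
    mean = np.asarray(mean, float)
    sd = np.zeros_like(mean) if sd is None else np.asarray(sd, float)
    df = pd.DataFrame({"bin": [f"b{i}" for i in range(len(mean))],
                       "age_Ma": ages, "mean": mean, "sd": sd,
                       "raw": mean, "n_occ": 10})
    return DiversityCurve(df, method=method, region=region)


def area_curve(ages, base, alpha=0.8, region="global"):
    return AreaCurve(np.asarray(ages, float), np.asarray(base, float),
                     alpha=alpha, region=region)


class TestNormalize:
    def test_divides_by_relative_area(self):
        div = div_curve([5.0, 15.0], [100.0, 100.0], sd=[10.0, 10.0])
        area = area_curve([5.0, 15.0], [1.0, 2.0], alpha=1.0)
        nd = normalize_diversity(div, area)
        assert np.allclose(nd.value, [100.0, 50.0])
        assert np.allclose(nd.sd, [10.0, 5.0])

    def test_unit_area_is_identity(self):
        div = div_curve([5.0, 15.0], [40.0, 60.0])
        nd = normalize_diversity(div, area_curve([5.0, 15.0], [1.0, 1.0]))
        assert np.allclose(nd.value, div.mean)

    def test_area_interpolated_to_bin_midpoints(self):
        div = div_curve([10.0], [100.0])
        area = area_curve([0.0, 20.0], [1.0, 3.0], alpha=1.0)
        nd = normalize_diversity(div, area)
        assert nd.value[0] == pytest.approx(50.0)


class TestPearsonWithCI:
    def test_perfect_line_and_exact_variance_explained(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2.0 * x + 3.0)
        assert res.r == pytest.approx(1.0)
        assert res.var_explained == pytest.approx(100.0)
        assert np.allclose(res.residuals, 0.0, atol=1e-10)

    def test_variance_explained_is_hundred_r_squared(self, rng):
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        res = pearson_with_ci(x, y)
        assert res.var_explained == 100.0 * res.r ** 2
        # an r printed as 0.86 explains 73.96% of variance
        assert 100.0 * 0.86 ** 2 == pytest.approx(73.96)

    def test_interval_ordering_and_bounds(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        res = pearson_with_ci(x, y)
        assert -1 <= res.ci_lo <= res.r <= res.ci_hi <= 1

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(40)
        y = 0.7 * x + rng.standard_normal(40)
        a = pearson_with_ci(x, y)
        b = pearson_with_ci(3.0 * x + 10.0, 0.5 * y - 2.0)
        assert a.r == pytest.approx(b.r)
        assert a.ci_lo == pytest.approx(b.ci_lo)

    def test_one_sigma_fisher_interval_covers_68_percent(self, rng):
        """Coverage simulation: bivariate normal rho=0.5, n=50."""
        rho, n, reps = 0.5, 50, 2000
        cov = np.array([[1.0, rho], [rho, 1.0]])
        hits = 0
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = pearson_with_ci(xy[:, 0], xy[:, 1])
            hits += res.ci_lo <= rho <= res.ci_hi
        assert abs(hits / reps - 0.683) < 0.03

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 6.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0, np.nan])
        res = pearson_with_ci(x, y)
        assert res.n_points == 4
        assert res.r == pytest.approx(1.0)


class TestMcCorrelation:
    def make_pair(self, n=60, seed=0, div_sd=0.1, sn_sig=0.1):
        rng = np.random.default_rng(seed)
        ages = np.arange(0.0, 5.0 * n, 5.0) + 2.5
        grid = np.arange(0.0, 5.0 * n + 1.0)
        rate = 1.0 + 0.4 * np.sin(grid / 23.0) + 0.2 * np.cos(grid / 7.0)
        sn = SNRateCurve(grid, rate, sigma=np.full(grid.size, sn_sig))
        fc = exp_memory_forcing(sn, 15.0)
        gamma = np.interp(ages, fc.ages, fc.gamma)
        values = 2.0 * gamma * np.exp(rng.normal(0, 0.05, ages.size))
        from paleosn.inference import NormalizedDiversity
        nd = NormalizedDiversity(ages, values,
                                 np.full(ages.size, div_sd * values.mean()))
        return nd, sn

    def test_zero_uncertainty_falls_back_to_fisher(self):
        nd, sn = self.make_pair(div_sd=0.0, sn_sig=0.0)
        nd.sd[:] = 0.0
        sn.sigma = None
        with pytest.warns(UserWarning, match="Fisher"):
            res = mc_correlation(nd, sn, lam=15.0, n_draws=50, seed=0)
        assert res.method == "fisher"

    def test_same_seed_bitwise_reproducible(self):
        nd, sn = self.make_pair()
        a = mc_correlation(nd, sn, lam=15.0, n_draws=200, seed=42)
        b = mc_correlation(nd, sn, lam=15.0, n_draws=200, seed=42)
        assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)

    def test_interval_comparable_to_fisher(self):
        nd, sn = self.make_pair(div_sd=0.08, sn_sig=0.08)
        mc = mc_correlation(nd, sn, lam=15.0, n_draws=1500, seed=3)
        width_mc = mc.ci_hi - mc.ci_lo
        assert 0 < width_mc < 0.5
        assert mc.method == "montecarlo"


def make_sn(n=500, seed=0, sigma=None):
    rng = np.random.default_rng(seed)
    grid = np.arange(float(n))
    rate = np.clip(1.0 + 0.35 * np.sin(grid / 19.0) +
                   0.25 * rng.standard_normal(n), 0.05, None)
    sig = np.full(n, sigma) if sigma is not None else None
    return SNRateCurve(grid, rate, sigma=sig)


class TestGridScan:
    def test_row_count_contract(self):
        ages = np.arange(2.5, 500.0, 5.0)
        div = {"global": div_curve(ages, 50 + 10 * np.sin(ages / 40))}
        areas = {"maps": area_curve(ages, 1 + 0.2 * np.cos(ages / 60)),
                 "sealevel": area_curve(ages, 1 + 0.1 * np.sin(ages / 80))}
        scan = grid_scan(div, areas, make_sn(), lambdas=(10.0, 20.0, 40.0),
                         alphas=(0.6, 0.8, 1.0))
        assert len(scan.rows) == 1 * 2 * 3 * 3
        assert set(scan.rows.columns) >= {"curve_label", "area_source",
                                          "lambda_Myr", "alpha", "r",
                                          "var_explained_pct", "c_fit"}

    def test_constant_sn_rows_flagged_not_raised(self):
        ages = np.arange(2.5, 100.0, 5.0)
        div = {"global": div_curve(ages, 50 + 10 * np.sin(ages / 10))}
        areas = {"maps": area_curve(ages, np.full(ages.size, 1.0))}
        sn = SNRateCurve(np.arange(100.0), np.full(100, 1.0))
        scan = grid_scan(div, areas, sn, lambdas=(10.0,), alphas=(0.8,))
        assert np.isnan(scan.rows["r"]).all()
        assert (scan.rows["flag"] != "").all()

    def test_unit_area_leaves_correlation_unchanged(self):
        ages = np.arange(2.5, 300.0, 5.0)
        sn = make_sn(300, seed=2)
        fc = exp_memory_forcing(sn, 20.0)
        gamma = np.interp(ages, fc.ages, fc.gamma)
        div = {"d": div_curve(ages, 3.0 * gamma + 5.0)}
        areas = {"flat": area_curve(ages, np.ones(ages.size))}
        scan = grid_scan(div, areas, sn, lambdas=(20.0,), alphas=(0.8,))
        direct = pearson_with_ci(gamma, 3.0 * gamma + 5.0)
        assert scan.rows["r"].iloc[0] == pytest.approx(direct.r)

    def test_invalid_lambda_rejected(self):
        ages = np.arange(2.5, 100.0, 5.0)
        div = {"d": div_curve(ages, np.arange(ages.size) + 1.0)}
        areas = {"a": area_curve(ages, np.ones(ages.size))}
        with pytest.raises(ConfigurationError):
            grid_scan(div, areas, make_sn(100), lambdas=(0.0,),
                      alphas=(0.8,))

    def test_noise_free_truth_has_near_perfect_correlation(self):
        """End-to-end: diversity built exactly from the model at
        (lambda, alpha) must correlate >= 0.95 at the truth cell."""
        sn = make_sn(500, seed=5)
        fc = exp_memory_forcing(sn, 20.0)
        ages = np.arange(2.5, 500.0, 5.0)
        gamma = np.interp(ages, fc.ages, fc.gamma)
        base = 1.0 + 0.5 * np.sin(ages / 45.0)
        div = {"truth": div_curve(ages, np.round(4.0 * gamma * base ** 0.8))}
        areas = {"a": area_curve(ages, base)}
        scan = grid_scan(div, areas, sn, lambdas=(20.0,), alphas=(0.8,))
        assert scan.rows["r"].iloc[0] > 0.95


class TestRegionalConvergence:
    def forcing(self):
        return exp_memory_forcing(make_sn(200, seed=1), 15.0)

    def regional_inputs(self, distinct_areas=True):
        ages = np.arange(2.5, 200.0, 5.0)
        fc = self.forcing()
        gamma = np.interp(ages, fc.ages, fc.gamma)
        div, areas = {}, {}
        for i, region in enumerate(["NH", "SH", "tropics"]):
            base = 1.0 + (0.4 * np.sin(ages / (20.0 + 12.0 * i))
                          if distinct_areas else np.zeros(ages.size))
            div[region] = div_curve(ages, 3.0 * gamma * base ** 0.8,
                                    region=region)
            areas[region] = area_curve(ages, base, region=region)
        return div, areas, fc

    def test_identical_regions_have_zero_dispersion(self):
        div, areas, fc = self.regional_inputs(distinct_areas=False)
        res = regional_convergence(div, areas, fc)
        assert res.dispersion_before == pytest.approx(0.0, abs=1e-12)
        assert res.dispersion_after == pytest.approx(0.0, abs=1e-12)

    def test_normalization_removes_area_driven_scatter(self):
        div, areas, fc = self.regional_inputs()
        res = regional_convergence(div, areas, fc)
        assert res.dispersion_after < res.dispersion_before
        assert res.dispersion_after == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_detrend_matches_no_detrend(self):
        div, areas, fc = self.regional_inputs()
        plain = regional_convergence(div, areas, fc, detrend=False)
        detr = regional_convergence(div, areas, fc, detrend=True)
        # residual mean trend is ~0 here, so outlines agree closely
        assert np.allclose(plain.forcing_outline, detr.forcing_outline,
                           rtol=1e-6, atol=1e-6 *
                           np.abs(plain.forcing_outline).max())

    def test_region_mismatch_rejected(self):
        div, areas, fc = self.regional_inputs()
        del areas["SH"]
        with pytest.raises(ConfigurationError):
            regional_convergence(div, areas, fc)


def test_effective_sample_size_shrinks_for_smooth_series(rng):
    t = np.arange(200.0)
    smooth = np.sin(t / 30.0) + 0.05 * rng.standard_normal(200)
    white_x = rng.standard_normal(200)
    white_y = rng.standard_normal(200)
    assert effective_n_ar1(smooth, smooth) < 100
    assert effective_n_ar1(white_x, white_y) == pytest.approx(200, rel=0.2)
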