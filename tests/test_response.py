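"""Response curves, LOWESS smoothing, set-point estimation, ANOVA."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import shearpoint as sp
from shearpoint.response import ResponseCurve, lowess_fit


def measurement_frame(shears, values, images=None):
    n = len(shears)
    return pd.DataFrame(
        {
            "image": images if images is not None else np.zeros(n, dtype=int),
            "orientation_deg": values,
            "shear_dyn_cm2": shears,
        }
    )


def make_curve(x, y, smoothed=None, kind="orientation"):
    x = np.asarray(x, dtype=float)
    return ResponseCurve(
        bin_centers=x,
        mean=np.asarray(y, dtype=float),
        sem=np.zeros_like(x),
        n=np.ones_like(x),
        kind=kind,
        smoothed=None if smoothed is None else np.asarray(smoothed, dtype=float),
    )


class TestBinByShear:
    def test_constant_response_zero_sem(self):
        rng = np.random.default_rng(0)
        shears = rng.uniform(2, 60, 300)
        images = np.repeat(np.arange(10), 30)
        df = measurement_frame(shears, np.full(300, 17.0), images)
        curve = sp.bin_by_shear(df, n_bins=8)
        assert np.allclose(curve.mean, 17.0)
        assert np.allclose(curve.sem, 0.0)

    def test_uniform_orientations_average_45_per_bin(self):
        uni = replace(sp.HUVEC_MODEL, angle_concentration=0.0)
        frames = []
        for i, tau in enumerate(np.linspace(3, 58, 10)):
            scene = sp.sample_scene_at_shear(
                uni, tau, 1000, seed=50 + i, image_shape_px=sp.suggested_image_shape(1000)
            )
            frames.append(measurement_frame(np.full(1000, tau), scene.folded_angles(), np.full(1000, i)))
        curve = sp.bin_by_shear(pd.concat(frames), n_bins=10, per_image=False)
        assert np.all(np.abs(curve.mean - 45.0) < 2.0)

    def test_single_occupied_bin(self):
        df = measurement_frame(np.full(20, 10.0), np.arange(20.0))
        curve = sp.bin_by_shear(df, bin_edges=np.array([0.0, 20.0]))
        assert len(curve) == 1

    def test_empty_bins_dropped(self, huvec_chamber):
        df = measurement_frame(np.array([3.0, 3.5, 55.0]), np.array([40.0, 42.0, 44.0]))
        curve = sp.bin_by_shear(df, config=huvec_chamber, n_bins=15, per_image=False)
        assert len(curve) == 2  # only the two occupied bins survive

    def test_shear_derived_from_position_when_missing(self, huvec_chamber):
        df = pd.DataFrame(
            {"image": [0, 0], "orientation_deg": [30.0, 40.0], "x_cm": [0.0, 7.0]}
        )
        curve = sp.bin_by_shear(df, config=huvec_chamber, n_bins=4, per_image=False)
        assert curve.bin_centers[0] < curve.bin_centers[-1]

    def test_all_nan_measurements_error(self):
        df = measurement_frame(np.array([5.0]), np.array([np.nan]))
        with pytest.raises(ValueError):
            sp.bin_by_shear(df, n_bins=3)


class TestLowess:
    def test_reproduces_exact_line(self):
        x = np.linspace(2, 60, 15)
        y = 0.7 * x + 3.0
        curve = lowess_fit(x, y, frac=0.5, iterations=3)
        assert np.max(np.abs(curve - y)) < 1e-6

    def test_robust_iterations_suppress_single_outlier(self):
        rng = np.random.default_rng(1)
        x = np.arange(12.0)
        y = 5.0 + rng.normal(0, 0.05, 12)
        y[6] += 45.0
        sm = lowess_fit(x, y, frac=0.5, iterations=3)
        assert np.max(np.abs(sm - 5.0)) / 5.0 < 0.1

    def test_matches_reference_implementation_nonrobust(self):
        # statsmodels as independent oracle; frac chosen so both use the
        # same integer window size
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 20))
        y = np.sin(x) + rng.normal(0, 0.2, 20)
        for frac in (0.4, 0.6, 1.0):
            ref = sm_lowess(y, x, frac=frac, it=0, return_sorted=False)
            ours = lowess_fit(x, y, frac=frac, iterations=0)
            assert np.max(np.abs(ref - ours)) < 1e-10

    def test_frac_one_on_line_equals_global_fit(self):
        x = np.linspace(0, 10, 9)
        y = 2.0 * x - 1.0
        coeffs = np.polyfit(x, y, 1)
        assert np.allclose(lowess_fit(x, y, frac=1.0), np.polyval(coeffs, x))

    def test_too_few_bins_suggests_raw_curve(self):
        curve = make_curve([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="raw curve"):
            sp.lowess(curve)

    def test_invalid_frac(self):
        with pytest.raises(ValueError, match="frac"):
            lowess_fit(np.arange(5.0), np.arange(5.0), frac=0.0)


class TestEstimateSetPoint:
    def biphasic_curve(self):
        x = np.linspace(2, 60, 15)
        y = 45.0 - 25.0 * np.exp(-0.5 * ((x - 15.0) / 8.0) ** 2)
        return make_curve(x, y, smoothed=y)

    def test_optimum_of_biphasic_minimum(self):
        est = sp.estimate_set_point(self.biphasic_curve(), kind="orientation")
        assert est.optimum_shear_dyn_cm2 == pytest.approx(15.0, abs=1.0)
        assert est.range_lo_dyn_cm2 <= 15.0 <= est.range_hi_dyn_cm2
        assert not est.at_boundary

    def test_smad_like_maximum(self):
        x = np.linspace(2, 60, 15)
        y = 0.3 + 0.4 * np.exp(-0.5 * ((x - 15.0) / 8.0) ** 2)
        est = sp.estimate_set_point(make_curve(x, y, smoothed=y, kind="smad"))
        assert est.optimum_shear_dyn_cm2 == pytest.approx(15.0, abs=1.0)

    def test_monotone_curve_flags_boundary(self):
        x = np.linspace(2, 60, 10)
        y = x * 0.5
        est = sp.estimate_set_point(make_curve(x, y, smoothed=y), kind="min")
        assert est.at_boundary
        assert est.optimum_shear_dyn_cm2 == pytest.approx(2.0)

    def test_affine_invariance_of_location(self):
        base = self.biphasic_curve()
        est0 = sp.estimate_set_point(base, kind="orientation")
        y2 = 3.0 * base.smoothed + 11.0
        est1 = sp.estimate_set_point(
            make_curve(base.bin_centers, y2, smoothed=y2), kind="orientation"
        )
        assert est1.optimum_shear_dyn_cm2 == pytest.approx(est0.optimum_shear_dyn_cm2, rel=1e-9)
        assert est1.range_lo_dyn_cm2 == est0.range_lo_dyn_cm2
        assert est1.range_hi_dyn_cm2 == est0.range_hi_dyn_cm2

    def test_baseline_from_no_flow_value(self):
        est = sp.estimate_set_point(self.biphasic_curve(), kind="orientation", baseline=45.0)
        assert est.baseline == 45.0

    def test_requires_smoothed_curve(self):
        c = make_curve([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="smooth"):
            sp.estimate_set_point(c, kind="min")

    def test_recovery_example_on_generator(self):
        images, xs, _ = sp.simulate_dataset(
            sp.HUVEC_CHAMBER, sp.HUVEC_MODEL, n_positions=16, n_cells=100, seed=0
        )
        est = sp.run_pipeline(images, xs, sp.RunConfig()).set_point
        assert est.range_lo_dyn_cm2 <= 15.0 <= est.range_hi_dyn_cm2
        assert 7.5 <= est.range_lo_dyn_cm2 and est.range_hi_dyn_cm2 <= 24.0


class TestAnova:
    def test_hand_computed_f_statistic(self):
        f, p, d1, d2 = sp.anova_shear_effect([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0, rel=1e-12)
        assert (d1, d2) == (2, 6)
        # p from F(2, 6) distribution
        from scipy import stats

        assert p == pytest.approx(stats.f.sf(3.0, 2, 6), rel=1e-12)

    def test_identical_means_f_near_zero(self):
        g = [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [2.0, 1.0, 3.0]]
        f, _, _, _ = sp.anova_shear_effect(g)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_f_increases_monotonically_with_group_shift(self):
        rng = np.random.default_rng(3)
        base = [rng.normal(0, 1, 15) for _ in range(4)]
        fs = []
        for shift in (0.5, 1.0, 2.0, 4.0, 8.0):
            groups = [g.copy() for g in base]
            groups[0] = groups[0] + shift
            fs.append(sp.anova_shear_effect(groups)[0])
        assert np.all(np.diff(fs) > 0)

    def test_degenerate_zero_variance_equal_means(self):
        f, p, _, _ = sp.anova_shear_effect([[2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(f) and np.isnan(p)

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {"shear_dyn_cm2": [1, 1, 1, 5, 5, 5], "v": [1.0, 2.0, 3.0, 6.0, 7.0, 8.0]}
        )
        f, p, d1, d2 = sp.anova_shear_effect(df)
        assert (d1, d2) == (1, 4)
        assert f > 10

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            sp.anova_shear_effect([[1.0, 2.0]])

    def test_type_one_error_rate_under_uniform_null(self):
        # orientation has no shear dependence: rejections at alpha=0.05
        # should stay near nominal over 200 simulations
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            groups = [np.abs(rng.uniform(-90, 90, 25)) for _ in range(6)]
            _, p, _, _ = sp.anova_shear_effect(groups)
            rejections += p < 0.05
        assert rejections <= 20  # <= 10% of 200
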