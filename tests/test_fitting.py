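"""Metrics, OLS and GA calibration, bootstrap intervals, sklearn estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arealaw.entropy_model import EntropyCoefficients
from arealaw.fitting import (
    AreaLawEntropyRegressor,
    CalibrationRecord,
    GAConfig,
    bootstrap_ci,
    dcor,
    design_matrix,
    design_row,
    fit_ga,
    fit_ols,
    mape,
    pairwise_delta_rmse,
    r2,
    rmse,
)
from arealaw.shapestats import SurfaceDescriptor
from arealaw.workbench import synthetic_regression_records

TRUE = EntropyCoefficients("area_deformation", 104.32, 3.078, 6.910, 21.456)


def noiseless_records(n=50, seed=0):
    return synthetic_regression_records(n, noise_sd=0.0, coefficients=TRUE, seed=seed)


class TestMetrics:
    def test_rmse_hand_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))  # 3.5355

    def test_mape_hand_value(self):
        assert mape([110.0, 110.0], [100.0, 100.0]) == pytest.approx(10.0)

    def test_perfect_linear_dependence(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        assert r2(y, y) == pytest.approx(1.0)
        assert dcor(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_r2_zero_variance_error(self):
        with pytest.raises(ValueError):
            r2([1.0, 2.0], [5.0, 5.0])

    def test_dcor_zero_distance_variance_returns_zero(self):
        assert dcor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0

    def test_dcor_bounded_and_permutation_symmetric(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        d = dcor(x, y)
        assert 0.0 <= d <= 1.0
        assert dcor(y, x) == pytest.approx(d, rel=1e-12)


class TestPairwiseDeltaRmse:
    def test_perfect_predictions(self):
        assert pairwise_delta_rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_three_point_toy_set(self):
        # pairs diffs pred (-1,-2,-1) vs obs (-1,-4,-3): sqrt((0+4+4)/3)
        got = pairwise_delta_rmse([1.0, 2.0, 3.0], [1.0, 2.0, 5.0])
        assert got == pytest.approx(np.sqrt(8.0 / 3.0))  # 1.63299

    def test_matches_exhaustive_enumeration(self, rng):
        """Closed form against the brute-force O(n²) pair sum."""
        pred = rng.normal(300, 50, size=30)
        obs = rng.normal(300, 50, size=30)
        diffs = [
            (pred[i] - pred[j]) - (obs[i] - obs[j])
            for i in range(30)
            for j in range(i + 1, 30)
        ]
        assert pairwise_delta_rmse(pred, obs) == pytest.approx(
            np.sqrt(np.mean(np.square(diffs))), rel=1e-12
        )

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=20),
        st.floats(min_value=-1e3, max_value=1e3),
    )
    def test_invariant_to_constant_offset(self, obs, shift):
        obs = np.asarray(obs)
        pred = obs * 1.1 + 3.0
        assert pairwise_delta_rmse(pred + shift, obs) == pytest.approx(
            pairwise_delta_rmse(pred, obs), rel=1e-9, abs=1e-9
        )


class TestDesignRow:
    def test_worked_examples(self):
        d = SurfaceDescriptor(1.0, 2 * 0.5 * np.log(0.5), 0.25 * np.log(0.25), 4.0)
        np.testing.assert_allclose(design_row(d), [1.0, 1.0, -0.693147, -0.346574], atol=1e-6)
        sphere = SurfaceDescriptor(15.205, 0.0, 0.0, 15.205)
        np.testing.assert_allclose(design_row(sphere), [1.0, 15.205, 0.0, 0.0])

    def test_dot_product_equals_prediction(self):
        from arealaw.entropy_model import predict_stharea

        d = SurfaceDescriptor(20.0, -3.0, -1.5, 50.0)
        theta = np.array([TRUE.s0, TRUE.a, TRUE.b, TRUE.c])
        assert design_row(d) @ theta == pytest.approx(predict_stharea(d, TRUE), rel=1e-12)


class TestFitOls:
    def test_noiseless_recovery_to_machine_precision(self):
        res = fit_ols(noiseless_records())
        co = res.coefficients
        for got, want in [(co.s0, TRUE.s0), (co.a, TRUE.a), (co.b, TRUE.b), (co.c, TRUE.c)]:
            assert got == pytest.approx(want, rel=1e-8)
        assert res.rmse < 1e-8 and res.r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_five_percent(self):
        recs = synthetic_regression_records(200, noise_sd=2.0, coefficients=TRUE, seed=5)
        co = fit_ols(recs).coefficients
        for got, want in [(co.s0, TRUE.s0), (co.a, TRUE.a), (co.b, TRUE.b), (co.c, TRUE.c)]:
            assert abs(got - want) / abs(want) < 0.05

    def test_is_the_exact_optimum(self):
        """No ±1% single-coefficient perturbation lowers the RMSE."""
        recs = synthetic_regression_records(200, noise_sd=10.0, coefficients=TRUE, seed=6)
        res = fit_ols(recs)
        x, y = design_matrix(recs)
        theta = np.array([res.coefficients.s0, res.coefficients.a,
                          res.coefficients.b, res.coefficients.c])
        base = rmse(x @ theta, y)
        for j in range(4):
            for factor in (0.99, 1.01):
                pert = theta.copy()
                pert[j] *= factor
                assert rmse(x @ pert, y) >= base

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_ols(noiseless_records(n=4))

    def test_rank_deficiency_names_collinear_column(self):
        records = []
        for i, r in enumerate(noiseless_records(30)):
            d = r.descriptor
            # sum_neg forced to zero everywhere -> zero column
            d2 = SurfaceDescriptor(d.area_spherical, d.sum_pos, 0.0, d.total_area, d.total_volume)
            records.append(CalibrationRecord(f"z{i}", d2, r.s_expt))
        with pytest.raises(np.linalg.LinAlgError, match="sum_neg"):
            fit_ols(records)


class TestFitGa:
    def test_matches_ols_on_noiseless_data(self):
        recs = noiseless_records(100, seed=2)
        ref = fit_ols(recs)
        res = fit_ga(recs, seed=99)
        assert res.rmse <= max(1.01 * ref.rmse, ref.rmse + 1.0)  # noiseless: near zero
        co, ct = res.coefficients, ref.coefficients
        assert co.s0 == pytest.approx(ct.s0, abs=1.0)
        assert co.a == pytest.approx(ct.a, rel=0.02)

    def test_within_one_percent_of_ols_on_noisy_data(self):
        recs = synthetic_regression_records(300, noise_sd=20.0, coefficients=TRUE, seed=3)
        ref = fit_ols(recs)
        res = fit_ga(recs, seed=77)
        assert res.rmse <= 1.01 * ref.rmse
        assert res.rmse >= ref.rmse  # OLS is the global optimum

    def test_fixed_seed_bit_identical(self):
        recs = synthetic_regression_records(80, noise_sd=15.0, coefficients=TRUE, seed=4)
        a = fit_ga(recs, seed=123)
        b = fit_ga(recs, seed=123)
        assert a.coefficients.as_dict() == b.coefficients.as_dict()
        assert a.rmse == b.rmse

    def test_bounds_excluding_optimum_pin_to_boundary(self):
        big = EntropyCoefficients("area_deformation", 400.0, 3.078, 6.910, 21.456)
        recs = synthetic_regression_records(60, noise_sd=0.0, coefficients=big, seed=8)
        res = fit_ga(recs, seed=1)  # S0 bound is ±200 < true 400
        assert res.coefficients.s0 == pytest.approx(200.0, abs=1e-6)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)


class TestBootstrapCi:
    def test_noiseless_intervals_have_zero_width(self):
        ci = bootstrap_ci(noiseless_records(60), fit_ols, n_boot=20, seed=1)
        for lo, hi in ci.values():
            assert hi - lo < 1e-6

    def test_intervals_contain_point_estimate(self):
        recs = synthetic_regression_records(150, noise_sd=20.0, coefficients=TRUE, seed=9)
        res = fit_ols(recs)
        ci = bootstrap_ci(recs, fit_ols, n_boot=100, seed=2)
        co = res.coefficients
        for name, value in [("s0", co.s0), ("a", co.a), ("b", co.b), ("c", co.c)]:
            lo, hi = ci[name]
            assert lo <= value <= hi

    def test_requires_at_least_two_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_ci(noiseless_records(20), fit_ols, n_boot=1)


class TestCalibrationRecord:
    def test_sanity_window_enforced(self):
        d = SurfaceDescriptor(10.0, 0.0, 0.0, 10.0)
        with pytest.raises(ValueError, match="sanity"):
            CalibrationRecord("bad", d, 50.0)

    def test_atypical_value_warns(self):
        d = SurfaceDescriptor(10.0, 0.0, 0.0, 10.0)
        with pytest.warns(UserWarning, match="typical"):
            CalibrationRecord("low", d, 150.0)


class TestAreaLawEntropyRegressor:
    @staticmethod
    def features_and_target(n=120, noise=5.0, seed=11):
        recs = synthetic_regression_records(n, noise_sd=noise, coefficients=TRUE, seed=seed)
        x, y = design_matrix(recs)
        return x[:, 1:], y

    def test_ols_matches_functional_api(self):
        recs = synthetic_regression_records(100, noise_sd=10.0, coefficients=TRUE, seed=13)
        x, y = design_matrix(recs)
        est = AreaLawEntropyRegressor(method="ols").fit(x[:, 1:], y)
        ref = fit_ols(recs).coefficients
        assert est.intercept_ == pytest.approx(ref.s0, rel=1e-10)
        np.testing.assert_allclose(est.coef_, [ref.a, ref.b, ref.c], rtol=1e-10)
        assert est.rmse_ == pytest.approx(fit_ols(recs).rmse, rel=1e-10)

    def test_predict_is_affine(self):
        x, y = self.features_and_target()
        est = AreaLawEntropyRegressor().fit(x, y)
        pred = est.predict(x[:5])
        np.testing.assert_allclose(pred, est.intercept_ + x[:5] @ est.coef_)

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = AreaLawEntropyRegressor(method="ga", generations=10, random_state=7)
        cl = clone(est)
        assert cl.get_params()["generations"] == 10
        cl.set_params(generations=20)
        assert cl.generations == 20

    def test_ga_method_reproducible(self):
        x, y = self.features_and_target(n=80)
        a = AreaLawEntropyRegressor(method="ga", generations=30, random_state=3).fit(x, y)
        b = AreaLawEntropyRegressor(method="ga", generations=30, random_state=3).fit(x, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_area_only_model_single_feature(self):
        rng = np.random.default_rng(0)
        area = rng.uniform(50, 400, size=60)
        y = 118.84 + 1.948 * area + rng.normal(0, 1, size=60)
        est = AreaLawEntropyRegressor(model="area_only").fit(area[:, None], y)
        assert est.coef_[0] == pytest.approx(1.948, rel=0.02)
        assert est.coefficients_.model_tag == "area_only"

    def test_wrong_feature_count_rejected(self):
        x, y = self.features_and_target(n=30)
        with pytest.raises(ValueError, match="feature"):
            AreaLawEntropyRegressor(model="area_only").fit(x, y)

    def test_score_is_r2(self):
        x, y = self.features_and_target()
        est = AreaLawEntropyRegressor().fit(x, y)
        assert est.score(x, y) == pytest.approx(est.r2_, rel=1e-6)
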