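import numpy as np
import pytest

from safy.forcing import ClimateForcing
from safy.params import SafyParameters
from safy.simulate import SafyTrajectory
from safy.yields import (
    DEFAULT_WINDOW,
    REFERENCE_REGRESSIONS,
    YieldRegression,
    YieldSample,
    compute_a_lai,
    confidence_bands,
    fit_yield_regression,
    predict_yield,
    validate_holdout,
)


def make_trajectory(lai):
    """Wrap a raw daily LAI series in a trajectory (other states zeroed)."""
    lai = np.asarray(lai, dtype=float)
    n = lai.size
    f = ClimateForcing(rg=np.full(n, 15.0), ta=np.full(n, 15.0))
    z = np.zeros(n)
    return SafyTrajectory(dam=z, lai=lai, gy=z, smt=z, params=SafyParameters(), forcing=f)


def make_cohort(a_lai, yields, **kw):
    return [
        YieldSample(plot_id=f"p{i}", a_lai=float(a), yield_measured=float(y), **kw)
        for i, (a, y) in enumerate(zip(a_lai, yields))
    ]


class TestComputeALai:
    def test_window_sum_cases(self):
        lai = np.zeros(270)
        assert compute_a_lai(make_trajectory(lai)) == 0.0
        lai[:] = 1.0
        assert compute_a_lai(make_trajectory(lai)) == 12.0  # 146..157 inclusive

    def test_triangular_ramp_hand_sum(self):
        lai = np.zeros(270)
        ramp = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.0])
        lai[145:157] = ramp  # season days 146..157
        assert compute_a_lai(make_trajectory(lai)) == pytest.approx(ramp.sum(), abs=1e-12)

    def test_additive_over_subwindows(self):
        rng = np.random.default_rng(3)
        traj = make_trajectory(rng.uniform(0, 5, 270))
        whole = compute_a_lai(traj, (146, 157))
        assert whole == pytest.approx(
            compute_a_lai(traj, (146, 150)) + compute_a_lai(traj, (151, 157)), rel=1e-12
        )

    def test_monotone_under_pointwise_increase(self):
        rng = np.random.default_rng(4)
        lai = rng.uniform(0, 5, 270)
        assert compute_a_lai(make_trajectory(lai + 0.5)) > compute_a_lai(make_trajectory(lai))

    def test_window_outside_season_rejected(self):
        traj = make_trajectory(np.zeros(150))
        with pytest.raises(ValueError):
            compute_a_lai(traj, (146, 157))
        with pytest.raises(ValueError):
            compute_a_lai(traj, (100, 90))


class TestFitYieldRegression:
    def test_exact_line(self):
        reg = fit_yield_regression(make_cohort([0, 10, 20], [10, 20, 30]))
        assert reg.slope == pytest.approx(1.0, abs=1e-10)
        assert reg.intercept == pytest.approx(10.0, abs=1e-9)
        assert reg.r2 == pytest.approx(1.0, abs=1e-12)

    def test_four_point_normal_equations(self):
        # hand solution: x=[0,2,4,6], y=[10,13,15,20]; Sxy=32, Sxx=20
        x = np.array([0.0, 2.0, 4.0, 6.0])
        y = np.array([10.0, 13.0, 15.0, 20.0])
        reg = fit_yield_regression(make_cohort(x, y))
        assert reg.slope == pytest.approx(1.6, abs=1e-12)
        assert reg.intercept == pytest.approx(14.5 - 1.6 * 3.0, abs=1e-12)

    def test_stratum_filtering(self):
        cohort = make_cohort([0, 10, 20], [10, 20, 30], crop="wheat") + make_cohort(
            [0, 10, 20], [5, 10, 15], crop="barley"
        )
        assert fit_yield_regression(cohort, "wheat").slope == pytest.approx(1.0)
        assert fit_yield_regression(cohort, "barley").slope == pytest.approx(0.5)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_yield_regression(make_cohort([5, 5, 5], [1, 2, 3]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_yield_regression(make_cohort([1, 2], [1, 2]))


class TestPredictYield:
    def test_reference_coefficients(self):
        assert predict_yield(REFERENCE_REGRESSIONS["all"], 0.0) == pytest.approx(17.97)
        assert predict_yield(REFERENCE_REGRESSIONS["all"], 100.0) == pytest.approx(50.97)
        assert predict_yield(REFERENCE_REGRESSIONS["irrigated"], 100.0) == pytest.approx(55.68)
        assert predict_yield(REFERENCE_REGRESSIONS["rainfed"], 100.0) == pytest.approx(61.05)

    def test_floored_at_zero(self):
        reg = YieldRegression("all", slope=-1.0, intercept=5.0, n=10, r2=0.5, residual_sd=1.0)
        assert predict_yield(reg, 50.0) == 0.0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 100, 40)
    y = 0.33 * x + 17.97 + rng.normal(0, 5, 40)
    return fit_yield_regression(make_cohort(x, y)), x, y


class TestConfidenceBands:
    def test_outer_contains_inner_everywhere(self, fitted):
        reg, _, _ = fitted
        bands = confidence_bands(reg, np.linspace(0, 120, 50))
        assert (bands["pred_lo"] < bands["mean_lo"]).all()
        assert (bands["pred_hi"] > bands["mean_hi"]).all()

    def test_narrowest_at_training_mean(self, fitted):
        reg, _, _ = fitted
        grid = np.linspace(0, 120, 241)
        bands = confidence_bands(reg, grid)
        width = bands["mean_hi"] - bands["mean_lo"]
        assert abs(grid[int(np.argmin(width))] - reg.x_mean) <= 1.0
        # widths grow monotonically with distance from the mean
        right = width[grid >= reg.x_mean].to_numpy()
        assert (np.diff(right) >= -1e-12).all()

    def test_halfwidth_at_mean_closed_form(self, fitted):
        from scipy import stats

        reg, _, _ = fitted
        bands = confidence_bands(reg, [reg.x_mean], level=0.95)
        t = stats.t.ppf(0.975, reg.n - 2)
        expect = t * reg.residual_sd * np.sqrt(1 / reg.n)
        half = (bands["mean_hi"] - bands["mean_lo"]).iloc[0] / 2
        assert half == pytest.approx(expect, rel=1e-9)

    def test_matches_statsmodels_prediction(self, fitted):
        """Closed-form bands must agree with statsmodels' get_prediction."""
        import statsmodels.api as sm

        reg, x, y = fitted
        grid = np.array([10.0, 50.0, 90.0])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        pred = res.get_prediction(sm.add_constant(grid))
        frame = pred.summary_frame(alpha=0.05)
        bands = confidence_bands(reg, grid, level=0.95)
        np.testing.assert_allclose(bands["mean_lo"], frame["mean_ci_lower"], rtol=1e-8)
        np.testing.assert_allclose(bands["pred_hi"], frame["obs_ci_upper"], rtol=1e-8)

    def test_invalid_level_rejected(self, fitted):
        reg, _, _ = fitted
        with pytest.raises(ValueError):
            confidence_bands(reg, [10.0], level=1.5)


class TestValidateHoldout:
    def test_noise_free_cohort_is_perfect(self):
        x = np.arange(30, dtype=float)
        cohort = make_cohort(x, 0.4 * x + 12.0)
        report = validate_holdout(cohort, n_repeats=5, seed=1)
        assert report.rmse_mean == pytest.approx(0.0, abs=1e-9)
        assert report.r2_mean == pytest.approx(1.0, abs=1e-9)
        assert len(report.rmse_runs) == 15  # every run reported

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 100, 31)
        cohort = make_cohort(x, 0.33 * x + 18 + rng.normal(0, 5, 31))
        a = validate_holdout(cohort, n_repeats=4, seed=7)
        b = validate_holdout(cohort, n_repeats=4, seed=7)
        assert (a.rmse_runs == b.rmse_runs).all()

    def test_rmse_tracks_known_noise_sd(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 100, 120)
        cohort = make_cohort(x, 0.33 * x + 18 + rng.normal(0, 5.0, 120))
        report = validate_holdout(cohort, n_repeats=20, seed=3)
        assert report.rmse_mean == pytest.approx(5.0, rel=0.20)

    def test_fold_count_exceeding_samples_rejected(self):
        cohort = make_cohort([1, 2], [1, 2])
        with pytest.raises(ValueError):
            validate_holdout(cohort, n_folds=3)


def test_model_file_round_trip(tmp_path):
    reg = fit_yield_regression(make_cohort([0, 10, 20, 30], [10, 21, 29, 41]))
    path = tmp_path / "model.txt"
    reg.to_file(path)
    back = YieldRegression.from_file(path)
    assert back == reg
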