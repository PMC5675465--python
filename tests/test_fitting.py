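"""Staged estimation: objectives, metrics, and scaled-down recovery checks.

Full-scale parameter recovery at the published protocol sizes lives in
the acceptance suite; here the same machinery is exercised on reduced
condition sets so each test stays fast.
"""
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from adenosim import (ModelParameters, PVTStage1Estimator,
                      SigmoidRecalibrationEstimator,
                      SleepTimingStage2Estimator, adjusted_r2, build_exp2,
                      fit_stage1, fit_stage3_recalibrate, make_pvt_exp1,
                      objective_pvt, rmse, simulate_protocol,
                      stage1_consistent_params)
from adenosim.errors import ConfigError
from adenosim.fitting import _damped_lm, _protocols_for

TWO_CONDITIONS = ("deprivation_88h", "tib4")


@pytest.fixture(scope="module")
def stage1_truth():
    return stage1_consistent_params(ModelParameters.pvt_fit())


@pytest.fixture(scope="module")
def clean_obs(stage1_truth):
    return make_pvt_exp1(params=stage1_truth, noise_sd=0.0,
                         conditions=TWO_CONDITIONS)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert adjusted_r2(y, y, 1) == 1.0
        assert rmse(y, y) == 0.0

    def test_mean_predictor_not_positive(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = np.full_like(y, y.mean())
        assert adjusted_r2(y, pred, 1) <= 0.0

    def test_hand_computed_toy_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = np.array([1.1, 1.9, 3.2, 3.9, 5.1])
        # SSE = 0.08, SST = 10, R^2 = 0.992; adj = 1 - 0.008*4/3
        assert adjusted_r2(y, pred, 1) == pytest.approx(1 - 0.008 * 4 / 3)
        assert rmse(y, pred) == pytest.approx(np.sqrt(0.08 / 5))

    def test_degenerate_inputs(self):
        y = np.array([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            adjusted_r2(y, y, 1)  # zero variance
        with pytest.raises(ValueError):
            adjusted_r2(np.arange(3.0), np.arange(3.0), 2)  # too few obs


class TestObjectivePvt:
    def test_zero_residuals_at_generating_parameters(self, stage1_truth,
                                                     clean_obs):
        protos = _protocols_for(TWO_CONDITIONS)
        res = objective_pvt(stage1_truth, protos, clean_obs)
        assert res.size == len(clean_obs)
        assert np.max(np.abs(res)) < 1e-9

    def test_sse_invariant_to_observation_ordering(self, stage1_truth,
                                                   clean_obs):
        protos = _protocols_for(TWO_CONDITIONS)
        shuffled = clean_obs.sample(frac=1.0, random_state=3)
        a = objective_pvt(stage1_truth, protos, clean_obs)
        b = objective_pvt(stage1_truth, protos, shuffled)
        assert np.sum(a ** 2) == pytest.approx(np.sum(b ** 2))

    def test_misaligned_times_rejected(self, stage1_truth, clean_obs):
        protos = _protocols_for(TWO_CONDITIONS)
        bad = clean_obs.copy()
        bad.loc[bad.index[0], "time_h"] += 0.5
        with pytest.raises(ConfigError):
            objective_pvt(stage1_truth, protos, bad)

    def test_smooth_in_sigmoid_width(self, stage1_truth, clean_obs):
        protos = _protocols_for(TWO_CONDITIONS)
        r0 = objective_pvt(stage1_truth, protos, clean_obs)
        r1 = objective_pvt(stage1_truth.replace(D_s=stage1_truth.D_s * 2),
                           protos, clean_obs)
        r2 = objective_pvt(
            stage1_truth.replace(D_s=stage1_truth.D_s * 2 + 1e-4),
            protos, clean_obs)
        assert np.max(np.abs(r1 - r0)) > 1e-3  # parameter matters
        assert np.max(np.abs(r2 - r1)) < 1e-2  # but smoothly


class TestDampedLM:
    def test_converges_on_quadratic(self):
        target = np.array([1.0, -2.0, 0.5])

        def resid(z):
            return z - target

        res = _damped_lm(resid, np.zeros(3))
        assert np.allclose(res.x, target, atol=1e-8)
        assert res.status in (2, 3)

    def test_cost_trace_monotone_on_rosenbrock_residuals(self):
        def resid(z):
            return np.array([10.0 * (z[1] - z[0] ** 2), 1.0 - z[0]])

        res = _damped_lm(resid, np.array([-1.2, 1.0]), max_nfev=2000)
        assert all(b < a for a, b in zip(res.cost_trace,
                                         res.cost_trace[1:]))
        assert np.allclose(res.x, [1.0, 1.0], atol=1e-6)


class TestStage1:
    def test_sklearn_params_round_trip(self):
        est = PVTStage1Estimator(max_nfev=10, dt=0.05)
        cloned = clone(est)
        assert cloned.get_params()["max_nfev"] == 10
        cloned.set_params(max_nfev=20)
        assert cloned.max_nfev == 20

    def test_gamma_cannot_be_free_while_tied(self, clean_obs):
        est = PVTStage1Estimator(free=("gamma", "D_mid"), tie_gamma=True)
        with pytest.raises(ConfigError):
            est.fit(clean_obs[["condition", "time_h"]], clean_obs["value"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_zero_noise_self_fit_recovers_truth(self, seed, stage1_truth,
                                                clean_obs):
        """Noise-free self-fits return the generating parameters from
        randomly perturbed starting points."""
        rng = np.random.default_rng(seed)
        start = stage1_truth.replace(
            D_mid=stage1_truth.D_mid + rng.uniform(-5, 5),
            D_s=stage1_truth.D_s * rng.uniform(0.8, 1.25),
            a=stage1_truth.a * rng.uniform(0.7, 1.4),
            phi=stage1_truth.phi + rng.uniform(-1, 1),
        )
        est = PVTStage1Estimator(
            free=("D_mid", "D_s", "a", "phi"), start=start,
            base_params=stage1_truth, max_nfev=150)
        est.fit(clean_obs[["condition", "time_h"]], clean_obs["value"])
        assert est.sse_ < 1e-6
        f = est.params_
        assert f.D_mid == pytest.approx(stage1_truth.D_mid, rel=1e-4)
        assert f.a == pytest.approx(stage1_truth.a, rel=1e-3)
        assert f.phi == pytest.approx(stage1_truth.phi, abs=1e-3)

    def test_fit_respects_affinity_bounds(self, stage1_truth):
        obs = make_pvt_exp1(params=stage1_truth, noise_sd=2.0, seed=5,
                            conditions=TWO_CONDITIONS)
        est = PVTStage1Estimator(max_nfev=60)
        est.fit(obs[["condition", "time_h"]], obs["value"])
        assert 1.0 <= est.params_.Kd1 <= 10.0
        assert 100.0 <= est.params_.Kd2 <= 10000.0
        assert est.params_.mu_wake > est.params_.mu_sleep > 0.0

    def test_wrapper_returns_fit_result(self, clean_obs, stage1_truth):
        result = fit_stage1(clean_obs, free=("D_mid", "D_s"),
                            base_params=stage1_truth, max_nfev=40)
        assert result.sse < 1e-6
        assert result.n_obs == len(clean_obs)
        assert result.n_params == 2

    def test_predict_matches_clean_observations(self, stage1_truth,
                                                clean_obs):
        est = PVTStage1Estimator(free=("D_mid",), start=stage1_truth,
                                 base_params=stage1_truth, max_nfev=20)
        est.fit(clean_obs[["condition", "time_h"]], clean_obs["value"])
        pred = est.predict(clean_obs[["condition", "time_h"]])
        assert np.allclose(pred, clean_obs["value"], atol=1e-6)


class TestStage2:
    def test_recovers_thresholds_on_narrow_domain(self):
        """Scaled-down grid recovery: 10 nights, domain bracketing truth."""
        truth = ModelParameters.full_fit()
        from adenosim import daily_sleep_durations
        traj = simulate_protocol(build_exp2(n_days=10), truth, dt=0.02)
        pairs = daily_sleep_durations(traj.bouts, n_days=10)
        durs = pd.DataFrame(pairs, columns=["day", "value"])
        est = SleepTimingStage2Estimator(
            lambda_range=(280.0, 305.0),
            d_sleep_range=(570.0, 576.0), d_wake_range=(552.0, 558.0))
        est.fit(durs["day"], durs["value"])
        assert abs(est.lambda_ - 291.0) <= est.spacing_["lambda_"] + 1e-9
        assert est.d_sleep_ == pytest.approx(572.7, abs=0.2)
        assert est.d_wake_ == pytest.approx(555.4, abs=0.2)
        assert est.sse_ < 1e-6
        assert est.grid_report_  # refinement trail retained

    def test_deterministic_repeat(self):
        truth = ModelParameters.full_fit()
        from adenosim import daily_sleep_durations
        traj = simulate_protocol(build_exp2(n_days=6), truth, dt=0.05)
        durs = pd.DataFrame(daily_sleep_durations(traj.bouts, n_days=6),
                            columns=["day", "value"])
        kw = dict(lambda_range=(285.0, 295.0), dt=0.05,
                  d_sleep_range=(571.0, 575.0),
                  d_wake_range=(553.0, 557.0))
        a = SleepTimingStage2Estimator(**kw).fit(durs["day"], durs["value"])
        b = SleepTimingStage2Estimator(**kw).fit(durs["day"], durs["value"])
        assert (a.lambda_, a.d_sleep_, a.d_wake_) == \
            (b.lambda_, b.d_sleep_, b.d_wake_)

    def test_degenerate_grid_rejected(self):
        est = SleepTimingStage2Estimator(lambda_range=(300.0, 300.0))
        with pytest.raises(ConfigError):
            est.fit(np.array([1, 2]), np.array([8.0, 8.0]))


class TestStage3:
    def test_recalibration_recovers_sigmoid(self):
        truth = ModelParameters.full_fit()
        obs = make_pvt_exp1(params=truth, noise_sd=2.0, seed=42)
        d_mid, d_s = fit_stage3_recalibrate(obs)
        assert d_mid == pytest.approx(583.2, rel=0.01)
        assert d_s == pytest.approx(5.872, rel=0.10)

    def test_sleep_outputs_decoupled_from_sigmoid(self):
        """Recalibrating the performance sigmoid cannot change sleep/wake
        outputs: bout structure is bit-identical across sigmoid values."""
        base = ModelParameters.full_fit()
        recal = base.replace(D_mid=579.3, D_s=5.603)
        proto = build_exp2(n_days=3)
        t1 = simulate_protocol(proto, base, dt=0.02)
        t2 = simulate_protocol(proto, recal, dt=0.02)
        assert [(b.onset, b.offset) for b in t1.bouts] == \
            [(b.onset, b.offset) for b in t2.bouts]

    def test_moves_from_pvt_fit_toward_data_optimum(self):
        """Starting from the PVT-only sigmoid, recalibration against data
        generated at the final values moves (D_mid, D_s) toward them."""
        truth = ModelParameters.full_fit()
        obs = make_pvt_exp1(params=truth, noise_sd=0.0)
        est = SigmoidRecalibrationEstimator(
            base_params=truth.replace(D_mid=579.3, D_s=5.603))
        est.fit(obs[["condition", "time_h"]], obs["value"])
        assert abs(est.d_mid_ - 583.2) < abs(579.3 - 583.2)
        assert abs(est.d_s_ - 5.872) < abs(5.603 - 5.872)
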