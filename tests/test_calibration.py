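"""EMG-driven calibration: moment prediction, cost decomposition, recovery."""

import numpy as np
import pytest

from myocot.emg_driven_calibration import (
    CalibrationProblem,
    activation_rmse,
    calibrate,
    calibration_cost,
    predicted_moments,
)
from myocot.model import LegModel
from myocot.mtu_mechanics import ActivationParams, MuscleTendonParams
from myocot.synthetic_gait import generate_trial


def _perturbed_start(truth_model: LegModel, seed: int, lopt_spread=0.10):
    """Truth model with only the adjustable classes perturbed (shape_A kept)."""
    rng = np.random.default_rng(seed)
    start = truth_model.copy()
    for name in start.muscle_names:
        m, a = start.muscles[name], start.activation[name]
        start.muscles[name] = MuscleTendonParams(
            m.name,
            m.f_max_iso,
            m.l_opt * (1 + lopt_spread * (2 * rng.random() - 1)),
            m.l_ts * (1 + 0.02 * (2 * rng.random() - 1)),
            m.alpha0,
            m.v_max,
            m.fast_twitch_fraction,
        )
        start.activation[name] = ActivationParams(
            emd=float(np.clip(a.emd + 0.01 * (2 * rng.random() - 1), 0.0, 0.1)),
            tau_act=float(np.clip(a.tau_act * (1 + 0.2 * (2 * rng.random() - 1)), 0.01, 0.1)),
            shape_A=a.shape_A,
            emg_scale=float(np.clip(a.emg_scale * (1 + 0.15 * (2 * rng.random() - 1)), 0.1, 1.5)),
        )
    return start


class TestPredictedMoments:
    def test_zero_emg_leaves_only_passive_moments(self, symmetric_trial):
        trial, truth = symmetric_trial
        import copy

        from myocot.mtu_mechanics import force_per_unit_activation
        from myocot.static_optimization import _cycle_gradient

        zeroed = copy.deepcopy(trial)
        zeroed.emg = type(trial.emg)(
            list(trial.emg.column_labels),
            trial.emg.time,
            np.zeros_like(trial.emg.values),
        )
        pred = predicted_moments(truth.model, zeroed)
        # oracle: passive-only moments summed muscle by muscle
        model = truth.model
        q = np.column_stack([trial.angles.column(d) for d in model.dof_names])
        qdot = _cycle_gradient(q, trial.angles.time)
        expected = np.zeros_like(pred.values)
        for name in model.muscle_names:
            l_mt, v_mt, r = model.geometry(name, q, qdot, model.dof_names)
            _, fp = force_per_unit_activation(l_mt, v_mt, model.muscles[name], model.curves)
            expected += r * fp[:, None]
        np.testing.assert_allclose(pred.values, expected, atol=1e-9)

    def test_forward_consistency_with_generator(self, symmetric_trial):
        trial, truth = symmetric_trial
        pred = predicted_moments(truth.model, trial)
        np.testing.assert_allclose(pred.values, trial.moments.values, atol=1e-9)

    def test_missing_channel_mapping_names_muscle(self, symmetric_trial):
        trial, truth = symmetric_trial
        model = truth.model.copy()
        del model.emg_map["soleus"]
        with pytest.raises(KeyError, match="soleus"):
            predicted_moments(model, trial)


class TestCalibrationCost:
    def test_zero_cost_at_truth_with_zero_penalty(self, symmetric_trial):
        trial, truth = symmetric_trial
        prob = CalibrationProblem(trials=[trial], model=truth.model, default_penalty=0.0)
        cost, terms = calibration_cost(prob.x0(), prob)
        assert cost == pytest.approx(0.0, abs=1e-12)
        assert terms["penalty"] == 0.0

    def test_single_penalty_term(self, symmetric_trial):
        trial, truth = symmetric_trial
        prob = CalibrationProblem(
            trials=[trial], model=truth.model, default_penalty=2.5
        )
        x = prob.x0()
        k = list(prob.adjustable).index("l_opt")  # first muscle's l_opt slot
        x[k] += 0.05
        cost, terms = calibration_cost(x, prob)
        assert terms["penalty"] == pytest.approx(2.5 * 0.05**2, rel=1e-9)

    def test_decomposition_matches_naive_loop_oracle(self, symmetric_trial):
        trial, truth = symmetric_trial
        prob = CalibrationProblem(trials=[trial], model=truth.model, default_penalty=1.0)
        rng = np.random.default_rng(3)
        lo, hi = prob.bounds()
        x = np.clip(prob.x0() + 0.03 * rng.standard_normal(len(lo)), lo, hi)
        cost, terms = calibration_cost(x, prob)
        # naive oracle: explicit python loops over every residual
        model = prob.apply(x)
        pred = predicted_moments(model, trial)
        moment = 0.0
        for d in model.dof_names:
            for pm, em in zip(pred.column(d), trial.moments.column(d)):
                moment += (pm - em) ** 2
        penalty = 0.0
        for xi, x0i in zip(x, prob.x0()):
            penalty += (xi - x0i) ** 2
        assert cost == pytest.approx(moment + penalty, rel=1e-9)
        assert terms["moment"] + terms["passive"] + terms["penalty"] == pytest.approx(
            cost, rel=1e-12
        )

    def test_out_of_bounds_rejected(self, symmetric_trial):
        trial, truth = symmetric_trial
        prob = CalibrationProblem(trials=[trial], model=truth.model)
        x = prob.x0()
        x[0] = 100.0
        with pytest.raises(ValueError, match="bounds"):
            calibration_cost(x, prob)


class TestCalibrate:
    def test_start_at_truth_converges_immediately(self, symmetric_trial):
        trial, truth = symmetric_trial
        prob = CalibrationProblem(trials=[trial], model=truth.model, default_penalty=0.0)
        res = calibrate(prob, max_iter=3)
        assert res.cost_final <= 1e-10
        assert all(v <= 1e-6 for v in res.moment_rmse.values())

    def test_noiseless_parameter_recovery_within_one_percent(self, leg_spec):
        trials = [
            generate_trial(leg_spec, v, {}, seed=k)[0]
            for k, v in enumerate((0.4, 0.6, 0.8))
        ]
        truth_model = leg_spec.truth_model()
        start = _perturbed_start(truth_model, seed=7)
        prob = CalibrationProblem(trials=trials, model=start, default_penalty=1e-8)
        res = calibrate(prob, max_iter=200)
        assert res.cost_final <= res.cost_initial
        for name in truth_model.muscle_names:
            t_m, c_m = truth_model.muscles[name], res.model.muscles[name]
            t_a, c_a = truth_model.activation[name], res.model.activation[name]
            assert c_m.l_opt / t_m.l_opt == pytest.approx(1.0, abs=0.01)
            assert c_m.l_ts / t_m.l_ts == pytest.approx(1.0, abs=0.01)
            assert c_a.emd == pytest.approx(t_a.emd, abs=0.001)
            assert c_a.tau_act / t_a.tau_act == pytest.approx(1.0, abs=0.01)
            assert c_a.emg_scale / t_a.emg_scale == pytest.approx(1.0, abs=0.01)

    def test_moment_noise_bounds_rmse(self, leg_spec):
        rng = np.random.default_rng(9)
        trial, truth = generate_trial(leg_spec, 0.6, {}, seed=5)
        noise_sd = 0.05 * np.std(trial.moments.values)
        noisy = trial.moments.values + rng.normal(0, noise_sd, trial.moments.values.shape)
        trial.moments = type(trial.moments)(
            list(trial.moments.column_labels), trial.moments.time, noisy
        )
        start = _perturbed_start(truth.model, seed=2, lopt_spread=0.05)
        prob = CalibrationProblem(trials=[trial], model=start, default_penalty=1e-8)
        res = calibrate(prob, max_iter=60)
        pooled_rmse = np.sqrt(np.mean([v**2 for v in res.moment_rmse.values()]))
        assert pooled_rmse <= 2.0 * noise_sd

    def test_parameters_stay_within_bounds(self, symmetric_trial):
        trial, truth = symmetric_trial
        start = _perturbed_start(truth.model, seed=4)
        prob = CalibrationProblem(trials=[trial], model=start)
        res = calibrate(prob, max_iter=20)
        lo, hi = prob.bounds()
        assert np.all(res.x >= lo - 1e-9) and np.all(res.x <= hi + 1e-9)


class TestActivationRmse:
    def test_identical_sets_give_zero(self):
        a = {"m1": np.linspace(0, 1, 101)}
        per, mean, sd = activation_rmse(a, {"m1": a["m1"].copy()})
        assert per["m1"] == 0.0 and mean == 0.0

    def test_constant_offset_closed_form(self):
        a = {"m1": np.zeros(101)}
        b = {"m1": np.full(101, 0.1)}
        per, mean, sd = activation_rmse(a, b)
        assert per["m1"] == pytest.approx(0.1, rel=1e-12)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(11)
        a = {f"m{i}": rng.random(101) for i in range(4)}
        b = {f"m{i}": rng.random(101) for i in range(4)}
        per, mean, sd = activation_rmse(a, b)
        for name in a:
            s = 0.0
            for x, y in zip(a[name], b[name]):
                s += (x - y) ** 2
            assert per[name] == pytest.approx(np.sqrt(s / 101), rel=1e-12)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            activation_rmse({"a": np.zeros(3)}, {"b": np.zeros(3)})
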