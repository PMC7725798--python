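"""Energetics models: component sums, sign laws, CoT algebra, transcription."""

import numpy as np
import pytest
import yaml
from importlib import resources

from myocot.metabolic_models import (
    MODEL_IDS,
    cost_of_transport,
    load_constants,
    muscle_mass,
    muscle_rates,
    rates_b04,
    rates_u03,
    rates_u10,
    whole_body_rate,
)
from myocot.mtu_mechanics import MuscleState, MuscleTendonParams

PARAMS = MuscleTendonParams(
    "m", f_max_iso=1000.0, l_opt=0.1, l_ts=0.2, fast_twitch_fraction=0.5
)


def make_state(a=0.5, u=None, lnorm=1.0, v_fiber=0.0, f_active=None, f_passive=0.0):
    """Single-frame muscle state with free control of the energetics inputs."""
    u = a if u is None else u
    n = 1
    fa = f_active if f_active is not None else a * PARAMS.f_max_iso
    arr = lambda x: np.full(n, float(x))
    return MuscleState(
        a=arr(a),
        u=arr(u),
        l_mt=arr(PARAMS.l_ts + lnorm * PARAMS.l_opt),
        v_mt=arr(v_fiber),
        fiber_length=arr(lnorm * PARAMS.l_opt),
        fiber_velocity=arr(v_fiber),
        f_active=arr(fa),
        f_passive=arr(f_passive),
        f_total=arr(fa + f_passive),
    )


class TestMuscleMass:
    def test_hand_arithmetic(self):
        c = load_constants("B04")
        # 1059.7 * (1000 / 0.25e6) * 0.1 = 0.42388 kg
        assert muscle_mass(PARAMS, c) == pytest.approx(0.42388, rel=1e-6)

    def test_linear_in_f_max(self):
        c = load_constants("U03")
        p2 = MuscleTendonParams("m", 2000.0, 0.1, 0.2, fast_twitch_fraction=0.5)
        assert muscle_mass(p2, c) == pytest.approx(2 * muscle_mass(PARAMS, c))

    def test_higher_specific_tension_means_less_mass_and_less_cost(self):
        lo = load_constants("B04", specific_tension=0.25e6)
        hi = load_constants("B04", specific_tension=0.5e6)
        assert muscle_mass(PARAMS, hi) < muscle_mass(PARAMS, lo)
        s = make_state(a=0.5, v_fiber=-0.02)
        assert np.sum(rates_b04(s, PARAMS, hi).total_rate) < np.sum(
            rates_b04(s, PARAMS, lo).total_rate
        )


@pytest.mark.parametrize("model_id", MODEL_IDS)
class TestSharedContracts:
    def test_rest_isometric_is_zero(self, model_id):
        c = load_constants(model_id)
        s = make_state(a=0.0, u=0.0, v_fiber=0.0, f_active=0.0)
        r = muscle_rates(s, PARAMS, c)
        assert np.allclose(r.total_rate, 0.0, atol=1e-12)

    def test_component_additivity_exact(self, model_id):
        rng = np.random.default_rng(1)
        c = load_constants(model_id)
        for _ in range(20):
            s = make_state(
                a=rng.random(),
                u=rng.random(),
                lnorm=rng.uniform(0.7, 1.4),
                v_fiber=rng.uniform(-0.3, 0.3),
                f_active=rng.uniform(0, 800),
            )
            r = muscle_rates(s, PARAMS, c)
            np.testing.assert_array_equal(
                r.total_rate,
                r.activation_heat_rate
                + r.maintenance_heat_rate
                + r.shortening_lengthening_heat_rate
                + r.work_rate,
            )

    def test_heat_components_nonnegative_at_rest_lengths(self, model_id):
        c = load_constants(model_id)
        s = make_state(a=0.6, u=0.7, lnorm=1.0, v_fiber=0.0)
        r = muscle_rates(s, PARAMS, c)
        assert np.all(r.activation_heat_rate >= 0)
        assert np.all(r.maintenance_heat_rate >= 0)

    def test_purity(self, model_id):
        c = load_constants(model_id)
        s = make_state(a=0.4, v_fiber=0.05)
        r1 = muscle_rates(s, PARAMS, c)
        r2 = muscle_rates(s, PARAMS, c)
        np.testing.assert_array_equal(r1.total_rate, r2.total_rate)

    def test_monotone_in_activation(self, model_id):
        c = load_constants(model_id)
        totals = []
        for a in (0.2, 0.5, 0.9):
            s = make_state(a=a, u=a, v_fiber=-0.02, f_active=a * 800.0)
            totals.append(float(muscle_rates(s, PARAMS, c).total_rate[0]))
        assert totals[0] < totals[1] < totals[2]


class TestSignLaws:
    def test_b04_lengthening_heat_nonpositive(self):
        c = load_constants("B04")
        s = make_state(a=0.5, v_fiber=+0.05, f_active=400.0)
        r = rates_b04(s, PARAMS, c)
        assert np.all(r.shortening_lengthening_heat_rate <= 0)

    @pytest.mark.parametrize("model_id", ["U03", "U10"])
    def test_umberger_lengthening_heat_nonnegative(self, model_id):
        c = load_constants(model_id)
        s = make_state(a=0.5, v_fiber=+0.05, f_active=400.0)
        r = muscle_rates(s, PARAMS, c)
        assert np.all(r.shortening_lengthening_heat_rate >= 0)

    def test_b04_eccentric_work_included_and_negative(self):
        c = load_constants("B04")
        s = make_state(a=0.5, v_fiber=+0.05, f_active=400.0)
        r = rates_b04(s, PARAMS, c)
        assert r.work_rate[0] == pytest.approx(-400.0 * 0.05)

    def test_u10_work_rate_zero_when_lengthening(self):
        c = load_constants("U10")
        s = make_state(a=0.5, v_fiber=+0.05, f_active=400.0)
        r = rates_u10(s, PARAMS, c)
        assert np.all(r.work_rate == 0.0)

    def test_u10_equals_u03_work_when_shortening(self):
        s = make_state(a=0.5, v_fiber=-0.08, f_active=400.0)
        w03 = rates_u03(s, PARAMS, load_constants("U03")).work_rate
        w10 = rates_u10(s, PARAMS, load_constants("U10")).work_rate
        np.testing.assert_allclose(w03, w10, rtol=1e-12)
        assert w10[0] > 0

    def test_shortening_work_positive_b04(self):
        c = load_constants("B04")
        s = make_state(a=0.8, v_fiber=-0.1, f_active=600.0)
        r = rates_b04(s, PARAMS, c)
        assert r.work_rate[0] == pytest.approx(600.0 * 0.1)


class TestDualTranscription:
    """Compare the shipped YAML coefficients against a second, independently
    written transcription of the published coefficient values."""

    B04_INDEPENDENT = {
        "activation_heat_slow": 40.0,
        "activation_heat_fast": 133.0,
        "maintenance_heat_slow": 74.0,
        "maintenance_heat_fast": 111.0,
        "shortening_coeff_iso": 0.16,
        "shortening_coeff_force": 0.18,
        "lengthening_coeff": 0.157,
    }
    UMBERGER_INDEPENDENT = {
        "act_maint_heat_fast_slope": 128.0,
        "act_maint_heat_intercept": 25.0,
        "act_maint_exponent": 0.6,
        "shortening_exponent": 2.0,
        "shortening_coeff_slow_numerator": 100.0,
        "shortening_coeff_fast_numerator": 153.0,
        "lengthening_coeff_factor": 4.0,
        "aerobic_scale": 1.5,
    }

    def test_b04_yaml_matches_independent_transcription(self):
        c = load_constants("B04")
        for k, v in self.B04_INDEPENDENT.items():
            assert c.coefficients[k] == pytest.approx(v), k

    @pytest.mark.parametrize("model_id", ["U03", "U10"])
    def test_umberger_yaml_matches_independent_transcription(self, model_id):
        c = load_constants(model_id)
        for k, v in self.UMBERGER_INDEPENDENT.items():
            assert c.coefficients[k] == pytest.approx(v), k

    def test_flags_encode_model_identity(self):
        assert load_constants("B04").lengthening_heat_sign == "negative"
        assert load_constants("U03").include_negative_work is True
        assert load_constants("U10").include_negative_work is False

    def test_density_and_tension_defaults(self):
        for mid in MODEL_IDS:
            c = load_constants(mid)
            assert c.muscle_density == pytest.approx(1059.7)
            assert c.specific_tension == pytest.approx(0.25e6)


class TestCostOfTransport:
    def test_constant_power_algebra(self):
        rate = np.full(101, 300.0)
        assert cost_of_transport(rate, 75.0, 1.0, 1.1) == pytest.approx(4.0)

    def test_doubling_speed_halves_cot(self):
        rate = np.full(101, 300.0)
        a = cost_of_transport(rate, 75.0, 0.5, 1.4)
        b = cost_of_transport(rate, 75.0, 1.0, 1.4)
        assert a == pytest.approx(2 * b)

    def test_resampling_changes_cot_below_point1_percent(self):
        t_f = 1.3
        t101 = np.linspace(0, t_f, 101)
        rate101 = 250 + 120 * np.sin(2 * np.pi * t101 / t_f) ** 2
        t201 = np.linspace(0, t_f, 201)
        rate201 = 250 + 120 * np.sin(2 * np.pi * t201 / t_f) ** 2
        a = cost_of_transport(rate101, 75, 0.6, t_f)
        b = cost_of_transport(rate201, 75, 0.6, t_f)
        assert abs(a - b) / b < 1e-3

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cost_of_transport(np.ones(101), 75.0, 0.0, 1.2)

    def test_mass_doubling_scale_law(self, symmetric_trial):
        """Doubling body mass, every f_max_iso (hence muscle mass) at the
        same kinematics doubles whole-body rate and leaves CoT unchanged."""
        trial, truth = symmetric_trial
        for mid in MODEL_IDS:
            c = load_constants(mid)
            series, series2 = [], []
            for name in truth.model.muscle_names:
                p = truth.model.muscles[name]
                p2 = MuscleTendonParams(
                    p.name, 2 * p.f_max_iso, p.l_opt, p.l_ts, p.alpha0, p.v_max,
                    p.fast_twitch_fraction,
                )
                s = truth.states[name]
                s2 = MuscleState(
                    a=s.a, u=s.u, l_mt=s.l_mt, v_mt=s.v_mt,
                    fiber_length=s.fiber_length, fiber_velocity=s.fiber_velocity,
                    f_active=2 * s.f_active, f_passive=2 * s.f_passive,
                    f_total=2 * s.f_total,
                )
                series.append(muscle_rates(s, p, c))
                series2.append(muscle_rates(s2, p2, c))
            r1 = whole_body_rate(series, trial.body_mass, c)
            r2 = whole_body_rate(series2, 2 * trial.body_mass, c)
            np.testing.assert_allclose(r2, 2 * r1, rtol=1e-9)
            cot1 = cost_of_transport(r1, trial.body_mass, trial.speed, trial.t_f)
            cot2 = cost_of_transport(r2, 2 * trial.body_mass, trial.speed, trial.t_f)
            assert cot2 == pytest.approx(cot1, rel=1e-9)


class TestWholeBody:
    def test_basal_rate_added(self):
        c = load_constants("B04")
        s = make_state(a=0.0, u=0.0, f_active=0.0)
        series = [rates_b04(s, PARAMS, c)]
        with_basal = whole_body_rate(series, 75.0, c, include_basal=True)
        without = whole_body_rate(series, 75.0, c, include_basal=False)
        np.testing.assert_allclose(with_basal - without, 1.2 * 75.0)

    def test_clamp_option_floors_negative_totals(self):
        c = load_constants("B04")
        # strong eccentric: negative work dominates -> negative total
        s = make_state(a=0.1, u=0.1, v_fiber=+0.5, f_active=900.0)
        series = [rates_b04(s, PARAMS, c)]
        assert series[0].total_rate[0] < 0
        clamped = whole_body_rate(series, 75.0, c, include_basal=False, clamp_muscle_totals=True)
        assert np.all(clamped >= 0)
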