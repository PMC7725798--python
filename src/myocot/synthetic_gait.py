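"""Self-consistent synthetic hemiparetic gait with known ground truth.

The generator is the stand-in for deposited treadmill data: it produces
gait trials whose every downstream quantity is known by construction, so
tests of the calibration, static-optimization, energetics and statistics
stages can compare against exact truth rather than against the pipeline
itself.

Construction guarantees, per trial:

* **Forward consistency.** Joint moments are *defined* as the sum of
  moment-arm-weighted muscle forces produced by the package's own
  excitation -> activation -> Hill-force chain applied to the truth
  parameters and truth envelopes, so re-predicting moments with the truth
  model reproduces them to machine precision.
* **Exact asymmetries.** Gait events are placed to realize the requested
  (signed) stance-time and double-support-time asymmetries exactly, and
  foot/pelvis fore-aft trajectories are adjusted so the linearly
  interpolated foot-to-pelvis distances at heel strike realize the
  requested step-length asymmetry exactly.
* **Known energetics.** The trial's cost of transport under each
  metabolic model is computed from the truth states and stored in the
  ground-truth record; an imposed linear CoT-versus-speed trend is
  realized by root-finding the per-speed activation amplitude scale.

The default leg is sagittal-plane: 3 DOFs (hip, knee, ankle flexion,
dorsiflexion positive at the ankle) actuated by 8 muscles with antagonist
pairs about every DOF — small enough for dense QP enumeration oracles,
structured like a reduced lower-limb model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt

from .emg_driven_calibration import predicted_moments
from .metabolic_models import (
    cost_of_transport,
    load_constants,
    muscle_rates,
    whole_body_rate,
)
from .model import LegModel, muscle_states_from_activations
from .motion_io import GaitEvents, GaitTrial, MotionTable
from .mtu_mechanics import (
    ActivationParams,
    MuscleState,
    MuscleTendonParams,
    activation_from_envelope,
    excitation_from_emg,
)
from .surrogate_geometry import SurrogatePolynomial, monomial_exponents

__all__ = [
    "SyntheticLegSpec",
    "SyntheticCohortSpec",
    "GroundTruth",
    "default_leg_spec",
    "generate_trial",
    "generate_cohort",
    "synthesize_raw_emg",
    "continuous_grf",
]

DOFS = ["hip_flexion", "knee_flexion", "ankle_flexion"]
N_CYCLE = 101


# ---------------------------------------------------------------------------
# leg specification

@dataclass
class WaveformSpec:
    """Smooth periodic envelope: raised-cosine bumps + co-contraction floor."""

    centers: tuple[float, ...]  # cycle fractions in [0, 1)
    widths: tuple[float, ...]  # cycle fractions
    amplitudes: tuple[float, ...]

    def evaluate(self, tau: np.ndarray, scale: float, floor: float) -> np.ndarray:
        e = np.full_like(tau, floor)
        for c, w, amp in zip(self.centers, self.widths, self.amplitudes):
            d = (tau - c + 0.5) % 1.0 - 0.5  # cyclic distance
            mask = np.abs(d) < w / 2
            e = e + np.where(mask, amp * 0.5 * (1 + np.cos(2 * np.pi * d / w)), 0.0)
        return np.clip(scale * e, 0.0, 1.0)


@dataclass
class SyntheticLegSpec:
    """Truth definition of a synthetic leg."""

    dof_names: list[str]
    muscles: dict[str, MuscleTendonParams]
    activation: dict[str, ActivationParams]
    geometry: dict[str, SurrogatePolynomial]  # truth polynomials, degree <= 3
    waveforms: dict[str, WaveformSpec]
    co_contraction: float = 0.02  # envelope floor (fraction of max excitation)

    def __post_init__(self) -> None:
        for dof_j, dof in enumerate(self.dof_names):
            signs = set()
            for name, surr in self.geometry.items():
                if dof in surr.spanned_dofs:
                    r = surr.moment_arms(np.zeros((1, len(surr.spanned_dofs))))
                    signs.add(np.sign(r[0, surr.spanned_dofs.index(dof)]))
            if not {1.0, -1.0} <= signs:
                raise ValueError(f"DOF {dof!r} lacks an antagonist muscle pair")

    def truth_model(self, emg_prefix: str = "emg_") -> LegModel:
        return LegModel(
            dof_names=list(self.dof_names),
            muscles=dict(self.muscles),
            activation=dict(self.activation),
            surrogates={k: _copy_surrogate(v) for k, v in self.geometry.items()},
            emg_map={name: emg_prefix + name for name in self.muscles},
        )


def _copy_surrogate(s: SurrogatePolynomial) -> SurrogatePolynomial:
    return SurrogatePolynomial(
        muscle=s.muscle,
        spanned_dofs=list(s.spanned_dofs),
        degree=s.degree,
        coefficients=s.coefficients.copy(),
    )


def _linear_surrogate(
    muscle: str, spanned: list[str], l0: float, arms: dict[str, float],
    quad: dict[str, float] | None = None,
) -> SurrogatePolynomial:
    """Truth length polynomial with constant (or mildly quadratic) moment arms.

    r_j = -dl/dq_j, so a positive moment arm appears as coefficient -r on q_j.
    """
    exps = monomial_exponents(len(spanned), 2)
    coeffs = np.zeros(len(exps))
    for i, e in enumerate(exps):
        if sum(e) == 0:
            coeffs[i] = l0
        elif sum(e) == 1:
            j = e.index(1)
            coeffs[i] = -arms[spanned[j]]
        elif sum(e) == 2 and max(e) == 2 and quad:
            j = e.index(2)
            coeffs[i] = quad.get(spanned[j], 0.0)
    return SurrogatePolynomial(muscle, spanned, 2, coeffs)


def default_leg_spec(co_contraction: float = 0.02) -> SyntheticLegSpec:
    """Sagittal 3-DOF, 8-muscle leg with antagonist pairs about every DOF."""
    H, K, A = DOFS

    def mtp(name, f, lo, lts, a0, vm, ft):
        return MuscleTendonParams(name, f, lo, lts, a0, vm, ft)

    muscles = {
        "iliopsoas": mtp("iliopsoas", 1500.0, 0.10, 0.13, 0.14, 10.0, 0.50),
        "glut_max": mtp("glut_max", 2500.0, 0.14, 0.18, 0.00, 10.0, 0.45),
        "rect_fem": mtp("rect_fem", 1200.0, 0.08, 0.35, 0.09, 10.0, 0.60),
        "hamstrings": mtp("hamstrings", 2200.0, 0.10, 0.33, 0.26, 10.0, 0.45),
        "vasti": mtp("vasti", 3500.0, 0.09, 0.12, 0.05, 10.0, 0.50),
        "gastroc": mtp("gastroc", 1800.0, 0.06, 0.39, 0.30, 10.0, 0.55),
        "soleus": mtp("soleus", 3000.0, 0.05, 0.26, 0.44, 10.0, 0.20),
        "tib_ant": mtp("tib_ant", 900.0, 0.07, 0.22, 0.09, 10.0, 0.30),
    }
    l0 = {n: m.l_ts + m.l_opt * np.cos(m.alpha0) for n, m in muscles.items()}
    geometry = {
        "iliopsoas": _linear_surrogate(
            "iliopsoas", [H], l0["iliopsoas"], {H: 0.050}, {H: 0.004}
        ),
        "glut_max": _linear_surrogate("glut_max", [H], l0["glut_max"], {H: -0.060}),
        "rect_fem": _linear_surrogate(
            "rect_fem", [H, K], l0["rect_fem"], {H: 0.040, K: -0.045}, {K: 0.003}
        ),
        "hamstrings": _linear_surrogate(
            "hamstrings", [H, K], l0["hamstrings"], {H: -0.055, K: 0.035}
        ),
        "vasti": _linear_surrogate("vasti", [K], l0["vasti"], {K: -0.045}, {K: 0.004}),
        "gastroc": _linear_surrogate(
            "gastroc", [K, A], l0["gastroc"], {K: 0.020, A: -0.050}
        ),
        "soleus": _linear_surrogate(
            "soleus", [A], l0["soleus"], {A: -0.045}, {A: 0.003}
        ),
        "tib_ant": _linear_surrogate("tib_ant", [A], l0["tib_ant"], {A: 0.040}),
    }
    activation = {
        "iliopsoas": ActivationParams(emd=0.030, tau_act=0.020, shape_A=0.8, emg_scale=0.90),
        "glut_max": ActivationParams(emd=0.040, tau_act=0.025, shape_A=0.0, emg_scale=0.85),
        "rect_fem": ActivationParams(emd=0.025, tau_act=0.015, shape_A=1.2, emg_scale=0.95),
        "hamstrings": ActivationParams(emd=0.035, tau_act=0.030, shape_A=0.5, emg_scale=0.80),
        "vasti": ActivationParams(emd=0.030, tau_act=0.020, shape_A=0.0, emg_scale=1.00),
        "gastroc": ActivationParams(emd=0.045, tau_act=0.025, shape_A=1.0, emg_scale=0.90),
        "soleus": ActivationParams(emd=0.040, tau_act=0.030, shape_A=0.6, emg_scale=0.95),
        "tib_ant": ActivationParams(emd=0.020, tau_act=0.015, shape_A=0.0, emg_scale=0.85),
    }
    waveforms = {
        "iliopsoas": WaveformSpec((0.62,), (0.30,), (0.45,)),
        "glut_max": WaveformSpec((0.06,), (0.28,), (0.40,)),
        "rect_fem": WaveformSpec((0.05, 0.63), (0.22, 0.18), (0.30, 0.25)),
        "hamstrings": WaveformSpec((0.95,), (0.28,), (0.45,)),
        "vasti": WaveformSpec((0.08,), (0.30,), (0.50,)),
        "gastroc": WaveformSpec((0.40,), (0.32,), (0.50,)),
        "soleus": WaveformSpec((0.42,), (0.34,), (0.55,)),
        "tib_ant": WaveformSpec((0.02, 0.68), (0.22, 0.28), (0.40, 0.30)),
    }
    return SyntheticLegSpec(
        dof_names=list(DOFS),
        muscles=muscles,
        activation=activation,
        geometry=geometry,
        waveforms=waveforms,
        co_contraction=co_contraction,
    )


# ---------------------------------------------------------------------------
# cohort specification and ground truth

@dataclass
class SyntheticCohortSpec:
    """Study conditions of one synthetic subject's trial set.

    Defaults emulate slow hemiparetic treadmill walking: speeds 0.35-0.8
    m/s, asymmetries that grow as speed drops, and a decreasing linear
    CoT-versus-speed trend realized exactly by the generator.
    """

    subject_id: str = "synth01"
    speeds: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8)
    trials_per_speed: int = 3
    body_mass: float = 75.0  # kg
    fugl_meyer: int = 32
    side_paretic: str = "right"
    # signed asymmetry rules, evaluated at each speed: base + slope * (speed - 0.6)
    step_asym_base: float = 0.06  # m
    step_asym_slope: float = -0.08  # m per m/s (worse when slower)
    stance_asym_base: float = 0.10  # s
    stance_asym_slope: float = -0.15
    ds_asym_base: float = 0.06  # s
    ds_asym_slope: float = -0.10
    emg_noise_sd: float = 0.0  # additive envelope noise SD (normalized units)
    amp_jitter: float = 0.03  # per-trial activation amplitude jitter (fraction)
    cot_trend: tuple[float, float] | None = (-3.0, 6.2)  # (slope, intercept), B04
    cot_trend_model: str = "B04"
    seed: int = 0

    def asymmetries(self, speed: float) -> dict[str, float]:
        d = speed - 0.6
        return {
            "step_length": self.step_asym_base + self.step_asym_slope * d,
            "stance_time": self.stance_asym_base + self.stance_asym_slope * d,
            "double_support": self.ds_asym_base + self.ds_asym_slope * d,
        }


@dataclass
class GroundTruth:
    """Everything the generator knows about one trial."""

    model: LegModel  # truth parameters and truth geometry
    envelopes: dict[str, np.ndarray]  # clean normalized envelopes
    excitations: dict[str, np.ndarray]
    activations: dict[str, np.ndarray]
    states: dict[str, MuscleState]
    moments: MotionTable
    events: GaitEvents
    asymmetries_signed: dict[str, float]
    amplitude_scale: float
    cot: dict[str, float]  # per metabolic model id (basal included)
    seed: int


# ---------------------------------------------------------------------------
# trial generation

def _joint_trajectories(tau: np.ndarray, speed: float) -> np.ndarray:
    """Smooth periodic sagittal joint angle curves (rad), q(0) = q(1)."""
    g = 0.75 + 0.45 * speed  # range grows modestly with speed
    hip = g * (0.05 + 0.35 * np.cos(2 * np.pi * tau))
    knee = g * (0.45 - 0.40 * np.cos(2 * np.pi * (tau - 0.70)))
    ankle = g * (-0.03 + 0.14 * np.sin(2 * np.pi * (tau - 0.05)))
    return np.column_stack([hip, knee, ankle])


def _place_events(
    t_f: float, stance_asym: float, ds_asym: float, stance_fraction: float = 0.62
) -> GaitEvents:
    """Events realizing the signed stance and double-support asymmetries exactly.

    Paretic heel strike is at t = 0.  With stance_np - stance_p = stance_asym
    and DS1 - DS2 = ds_asym, the non-paretic heel strike lands at
    h = (t_f + ds_asym - stance_asym) / 2.
    """
    s_mean = stance_fraction * t_f
    st_np = s_mean + stance_asym / 2.0
    st_p = s_mean - stance_asym / 2.0
    h = (t_f + ds_asym - stance_asym) / 2.0
    to_p = st_p
    to_np = (h + st_np) % t_f
    # the closed form assumes the usual gait topology
    if not (0 < h < st_p and h + st_np > t_f):
        raise ValueError(
            f"requested asymmetries (stance {stance_asym}, ds {ds_asym}) are not "
            f"realizable with cycle period {t_f}"
        )
    return GaitEvents(
        hs_paretic=0.0, to_paretic=to_p, hs_nonparetic=h, to_nonparetic=to_np, t_f=t_f
    )


def _foot_trajectory(
    t: np.ndarray, t_f: float, hs: float, step: float
) -> np.ndarray:
    """Fore-aft foot curve whose *interpolated* value at heel strike is exact.

    A cosine peaking at heel strike, with the two grid samples bracketing
    the heel strike shifted by a common offset so linear interpolation at
    the (generally off-grid) event time returns ``step`` exactly.
    """
    y = step * np.cos(2 * np.pi * (t - hs) / t_f)
    dt = t[1] - t[0]
    k = int(np.floor((hs % t_f) / dt))
    k1 = min(k + 1, len(t) - 1)
    frac = (hs % t_f) / dt - k
    interp0 = (1 - frac) * y[k] + frac * y[k1]
    y[k] += step - interp0
    if k1 != k:
        y[k1] += step - interp0
    return y


def _stance_grf(
    t: np.ndarray, t_f: float, hs: float, to: float, body_weight: float,
    ramp: float = 0.03,
) -> np.ndarray:
    """Vertical GRF: trapezoidal stance profile with sharp threshold crossings."""
    tau = (t - hs) % t_f
    stance = (to - hs) % t_f
    up = np.clip(tau / ramp, 0.0, 1.0)
    down = np.clip((stance - tau) / ramp, 0.0, 1.0)
    in_stance = tau <= stance
    return body_weight * np.where(in_stance, np.minimum(up, down), 0.0)


def generate_trial(
    leg: SyntheticLegSpec,
    speed: float,
    asymmetries: dict[str, float],
    seed: int = 0,
    *,
    subject_id: str = "synth01",
    body_mass: float = 75.0,
    fugl_meyer: int = 32,
    side_paretic: str = "right",
    amplitude_scale: float = 1.0,
    emg_noise_sd: float = 0.0,
    t_f: float | None = None,
) -> tuple[GaitTrial, GroundTruth]:
    """One fully self-consistent synthetic gait cycle.

    ``asymmetries`` carries the *signed* targets for keys ``step_length``
    (m), ``stance_time`` (s) and ``double_support`` (s); the corresponding
    outcome metrics return their absolute values exactly.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    rng = np.random.default_rng(seed)
    t_f = t_f if t_f is not None else (0.35 + 0.70 * speed) / speed
    t = np.linspace(0.0, t_f, N_CYCLE)
    tau = t / t_f
    dt = t[1] - t[0]

    model = leg.truth_model()
    q = _joint_trajectories(tau, speed)
    angles = MotionTable(list(leg.dof_names), t, q)

    envelopes = {
        name: leg.waveforms[name].evaluate(tau, amplitude_scale, leg.co_contraction)
        for name in model.muscle_names
    }
    for e in envelopes.values():
        e[-1] = e[0]  # enforce exact periodicity of the sampled envelope

    excitations, activations = {}, {}
    states: dict[str, MuscleState] = {}
    qdot = None
    for name in model.muscle_names:
        p = model.activation[name]
        excitations[name] = excitation_from_emg(envelopes[name], p, dt)
        activations[name] = activation_from_envelope(envelopes[name], p, dt)
    from .static_optimization import _cycle_gradient

    qdot = _cycle_gradient(q, t)
    for name in model.muscle_names:
        states[name] = muscle_states_from_activations(
            model, name, activations[name], excitations[name], q, qdot, leg.dof_names
        )

    emg_clean = MotionTable(
        [model.emg_map[n] for n in model.muscle_names],
        t,
        np.column_stack([envelopes[n] for n in model.muscle_names]),
    )

    ev = _place_events(
        t_f, asymmetries.get("stance_time", 0.0), asymmetries.get("double_support", 0.0)
    )
    step_asym = asymmetries.get("step_length", 0.0)
    base_step = 0.25
    d_np = base_step + step_asym / 2.0
    d_p = base_step - step_asym / 2.0
    foot_p = _foot_trajectory(t, t_f, ev.hs_paretic, d_p)
    foot_np = _foot_trajectory(t, t_f, ev.hs_nonparetic, d_np)
    pelvis = np.zeros(N_CYCLE)
    foot_L = foot_p if side_paretic == "left" else foot_np
    foot_R = foot_np if side_paretic == "left" else foot_p

    bw = body_mass * 9.81
    hs_p, to_p = ev.hs_paretic, ev.to_paretic
    hs_np, to_np_t = ev.hs_nonparetic, ev.to_nonparetic
    grf_p = _stance_grf(t, t_f, hs_p, to_p, 1.05 * bw)
    grf_np = _stance_grf(t, t_f, hs_np, to_np_t, 1.05 * bw)
    shear_p = 0.12 * grf_p * np.sin(2 * np.pi * tau)
    shear_np = 0.12 * grf_np * np.sin(2 * np.pi * tau)
    if side_paretic == "left":
        grf_cols = {
            "grf_left_vy": grf_p, "grf_left_fx": shear_p,
            "grf_right_vy": grf_np, "grf_right_fx": shear_np,
        }
    else:
        grf_cols = {
            "grf_left_vy": grf_np, "grf_left_fx": shear_np,
            "grf_right_vy": grf_p, "grf_right_fx": shear_p,
        }
    grf = MotionTable.from_arrays(t, grf_cols)

    trial = GaitTrial(
        subject_id=subject_id,
        side_paretic=side_paretic,
        speed=speed,
        body_mass=body_mass,
        fugl_meyer=fugl_meyer,
        t_f=t_f,
        angles=angles,
        moments=MotionTable(list(leg.dof_names), t, np.zeros_like(q)),
        grf=grf,
        emg=emg_clean,
        pelvis_pos=pelvis,
        foot_pos_L=foot_L,
        foot_pos_R=foot_R,
        events=ev,
    )
    # the trial's "inverse dynamics" moments are DEFINED as the truth-model
    # EMG-driven prediction, so forward consistency is exact by construction
    trial.moments = predicted_moments(model, trial)

    cot = {}
    for mid in ("B04", "U03", "U10"):
        consts = load_constants(mid)
        series = [
            muscle_rates(states[n], model.muscles[n], consts)
            for n in model.muscle_names
        ]
        rate = whole_body_rate(series, body_mass, consts, include_basal=True)
        cot[mid] = cost_of_transport(rate, body_mass, speed, t_f)

    truth = GroundTruth(
        model=model,
        envelopes=envelopes,
        excitations=excitations,
        activations=activations,
        states=states,
        moments=trial.moments,
        events=ev,
        asymmetries_signed=dict(asymmetries),
        amplitude_scale=amplitude_scale,
        cot=cot,
        seed=seed,
    )

    if emg_noise_sd > 0:
        noisy = np.clip(
            emg_clean.values + rng.normal(0.0, emg_noise_sd, emg_clean.values.shape),
            0.0,
            1.0,
        )
        trial.emg = MotionTable(list(emg_clean.column_labels), t, noisy)
    return trial, truth


def _cot_at_scale(
    leg: SyntheticLegSpec, speed: float, scale: float, body_mass: float, model_id: str
) -> float:
    trial, truth = generate_trial(
        leg, speed, {}, seed=0, body_mass=body_mass, amplitude_scale=scale
    )
    return truth.cot[model_id]


def generate_cohort(
    cohort: SyntheticCohortSpec, leg: SyntheticLegSpec | None = None
) -> list[tuple[GaitTrial, GroundTruth]]:
    """Deterministic trial set over the cohort's speeds.

    If the cohort imposes a CoT trend, the per-speed activation amplitude
    scale is found by bisection so the clean trial's CoT under the trend's
    metabolic model equals slope * speed + intercept; per-trial amplitude
    jitter then scatters trials around the trend line.
    """
    leg = leg if leg is not None else default_leg_spec()
    rng = np.random.default_rng(cohort.seed)
    out: list[tuple[GaitTrial, GroundTruth]] = []
    for speed in cohort.speeds:
        if cohort.cot_trend is not None:
            slope, intercept = cohort.cot_trend
            target = slope * speed + intercept
            f = lambda s: (
                _cot_at_scale(leg, speed, s, cohort.body_mass, cohort.cot_trend_model)
                - target
            )
            scale = brentq(f, 0.05, 2.0, xtol=1e-6)
        else:
            scale = 1.0
        asym = cohort.asymmetries(speed)
        for k in range(cohort.trials_per_speed):
            jitter = 1.0 + cohort.amp_jitter * rng.standard_normal()
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trial, truth = generate_trial(
                leg,
                speed,
                asym,
                seed=trial_seed,
                subject_id=cohort.subject_id,
                body_mass=cohort.body_mass,
                fugl_meyer=cohort.fugl_meyer,
                side_paretic=cohort.side_paretic,
                amplitude_scale=scale * jitter,
                emg_noise_sd=cohort.emg_noise_sd,
            )
            trial.meta["trial_index"] = k
            out.append((trial, truth))
    return out


# ---------------------------------------------------------------------------
# raw EMG synthesis (for testing the envelope pipeline)

def synthesize_raw_emg(
    envelope: np.ndarray,
    t_f: float,
    fs: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    band: tuple[float, float] = (40.0, 150.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw EMG = envelope x band-limited carrier + additive Gaussian noise.

    The 101-sample envelope is upsampled to ``fs``; the carrier is unit-RMS
    band-limited (40-150 Hz) Gaussian noise.  Returns (t, raw, envelope_fs).
    """
    rng = np.random.default_rng(seed)
    n = int(round(t_f * fs))
    t = np.arange(n) / fs
    env_t = np.linspace(0.0, t_f, len(envelope))
    env = np.interp(t, env_t, np.asarray(envelope, float))
    white = rng.standard_normal(n)
    sos = butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="bandpass", output="sos")
    carrier = sosfiltfilt(sos, white)
    carrier = carrier / np.sqrt(np.mean(carrier**2))
    raw = env * carrier + noise_sd * rng.standard_normal(n)
    return t, raw, env


def continuous_grf(
    events_per_cycle: GaitEvents,
    n_cycles: int,
    fs: float = 1000.0,
    body_weight: float = 735.0,
) -> tuple[MotionTable, dict[str, list[float]]]:
    """Multi-cycle two-foot vertical GRF record plus its true event times.

    For testing event detection/segmentation against ground truth.
    """
    t_f = events_per_cycle.t_f
    n = int(round(n_cycles * t_f * fs))
    t = np.arange(n) / fs
    grf_p = _stance_grf(t, t_f, events_per_cycle.hs_paretic, events_per_cycle.to_paretic, body_weight)
    grf_np = _stance_grf(
        t, t_f, events_per_cycle.hs_nonparetic, events_per_cycle.to_nonparetic, body_weight
    )
    table = MotionTable.from_arrays(
        t, {"grf_right_vy": grf_p, "grf_left_vy": grf_np}
    )
    truth = {
        "hs_right": [
            events_per_cycle.hs_paretic + k * t_f for k in range(n_cycles)
        ],
        "hs_left": [
            events_per_cycle.hs_nonparetic + k * t_f for k in range(n_cycles)
        ],
    }
    return table, truth
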