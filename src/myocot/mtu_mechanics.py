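"""EMG-to-activation dynamics and rigid-tendon Hill-type muscle mechanics.

This is the shared engine for all three activation-estimation approaches
(static optimization on a generic model, static optimization on a calibrated
model, and the fully EMG-driven model) and for the metabolic energetics
models downstream.

The muscle-tendon unit is a Hill-type actuator with a rigid tendon: the
tendon length is fixed at its slack length, so fiber length and velocity
follow algebraically from the muscle-tendon length and velocity, and tendon
force is affine in activation at given kinematics.  That affinity is what
makes per-frame static optimization an exact quadratic program.

Activation chain, per muscle:

    normalized EMG envelope e(t)
      -> excitation u(t) = s_emg * e(t - d_emd)      (cyclic shift, scale)
      -> first-order activation dynamics, tau_deact = 4 * tau_act
      -> optional exponential non-linearization with shape factor A

Force: f_total = (a * F_iso * fl(lnorm) * fv(vnorm) + F_iso * fp(lnorm)) * cos(pennation),
with a Gaussian-type active force-length bell, an exponential passive curve
with onset at optimal fiber length, and a Hill hyperbola force-velocity
curve whose eccentric branch saturates at 1.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivationParams",
    "MuscleTendonParams",
    "MuscleState",
    "CurveCoefficients",
    "excitation_from_emg",
    "activation_dynamics",
    "nonlinearize",
    "activation_from_envelope",
    "fiber_kinematics",
    "muscle_force",
    "force_length_active",
    "force_length_passive",
    "force_velocity",
]


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ActivationParams:
    """EMG-to-activation parameters (the neural half of calibration).

    emd: electromechanical delay, s in [0, 0.1]
    tau_act: activation time constant, s in [0.01, 0.1]; deactivation is 4x slower
    shape_A: non-linearization shape factor in (0, 3], or 0 for a linear map
    emg_scale: multiplicative EMG scale factor in (0, 1.5]
    """

    emd: float = 0.0
    tau_act: float = 0.015
    shape_A: float = 0.0
    emg_scale: float = 1.0

    def __post_init__(self) -> None:
        _check_range("emd", self.emd, 0.0, 0.1)
        _check_range("tau_act", self.tau_act, 0.01, 0.1)
        if not (self.shape_A == 0.0 or 0.0 < self.shape_A <= 3.0):
            raise ValueError(f"shape_A={self.shape_A} must be 0 or in (0, 3]")
        if not 0.0 < self.emg_scale <= 1.5:
            raise ValueError(f"emg_scale={self.emg_scale} outside (0, 1.5]")


@dataclass(frozen=True)
class MuscleTendonParams:
    """Hill-model parameters of one muscle-tendon actuator."""

    name: str
    f_max_iso: float  # N
    l_opt: float  # optimal fiber length, m
    l_ts: float  # tendon slack length, m
    alpha0: float = 0.0  # pennation at optimal fiber length, rad
    v_max: float = 10.0  # max shortening velocity, l_opt/s
    fast_twitch_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.f_max_iso <= 0 or self.l_opt <= 0 or self.l_ts <= 0:
            raise ValueError("f_max_iso, l_opt and l_ts must be positive")
        _check_range("alpha0", self.alpha0, 0.0, 0.6)
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        _check_range("fast_twitch_fraction", self.fast_twitch_fraction, 0.0, 1.0)


@dataclass
class MuscleState:
    """Per-frame mechanical state series of one muscle over the cycle."""

    a: np.ndarray  # activation [0, 1]
    u: np.ndarray  # excitation [0, 1]
    l_mt: np.ndarray  # m
    v_mt: np.ndarray  # m/s
    fiber_length: np.ndarray  # m
    fiber_velocity: np.ndarray  # m/s (positive = lengthening)
    f_active: np.ndarray  # N, along the fiber
    f_passive: np.ndarray  # N, along the fiber
    f_total: np.ndarray  # N, along the tendon

    def __post_init__(self) -> None:
        if np.any(self.a < -1e-12) or np.any(self.a > 1 + 1e-12):
            raise ValueError("activation outside [0, 1]")


@dataclass(frozen=True)
class CurveCoefficients:
    """Coefficients of the Hill-model curves (all dimensionless)."""

    fl_width: float = 0.45  # Gaussian bell width of active force-length
    fp_gain: float = 5.0 / 0.7  # passive exponential rate
    fp_norm: float = float(np.expm1(5.0))  # passive force 1.0 at lnorm = 1.7
    fv_shape: float = 0.25  # Hill hyperbola curvature (shortening)
    fv_ecc_max: float = 1.4  # eccentric force plateau


_DEFAULT_CURVES = CurveCoefficients()


def excitation_from_emg(
    envelope: np.ndarray, params: ActivationParams, dt: float
) -> np.ndarray:
    """Excitation = scaled, electromechanically delayed envelope.

    The delay is applied as a cyclic shift over the gait cycle (the envelope
    is one cycle of a periodic signal); fractional-sample delays are linearly
    interpolated.  Output is clipped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    e = np.asarray(envelope, dtype=float)
    n = e.shape[0]
    shift = params.emd / dt  # samples, possibly fractional
    idx = (np.arange(n) - shift) % n
    i0 = np.floor(idx).astype(int) % n
    i1 = (i0 + 1) % n
    frac = idx - np.floor(idx)
    delayed = (1.0 - frac) * e[i0] + frac * e[i1]
    return np.clip(params.emg_scale * delayed, 0.0, 1.0)


def activation_dynamics(
    excitation: np.ndarray,
    tau_act: float,
    dt: float,
    deact_ratio: float = 4.0,
    n_cycles: int = 2,
) -> np.ndarray:
    """First-order activation dynamics, backward Euler, cyclic steady state.

    da/dt = (u - a) / tau with tau = tau_act while activating (u > a) and
    deact_ratio * tau_act while deactivating.  The cycle is iterated
    ``n_cycles`` times from a(0) = u(0) and the last pass is returned, so the
    result is (near) periodic.
    """
    if tau_act <= 0:
        raise ValueError("tau_act must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.clip(np.asarray(excitation, dtype=float), 0.0, 1.0)
    n = u.shape[0]
    a = np.empty(n)
    a_prev = float(u[0])
    for _ in range(n_cycles):
        for k in range(n):
            tau = tau_act if u[k] > a_prev else deact_ratio * tau_act
            # backward Euler: a_k = (a_{k-1} + dt/tau * u_k) / (1 + dt/tau)
            r = dt / tau
            a_prev = (a_prev + r * u[k]) / (1.0 + r)
            a[k] = a_prev
        a_prev = a[-1]
    return np.clip(a, 0.0, 1.0)


def nonlinearize(a_linear: np.ndarray, shape_A: float) -> np.ndarray:
    """Exponential activation non-linearization, fixed at 0->0 and 1->1.

    a = (exp(A * a_lin) - 1) / (exp(A) - 1) for A > 0; identity for A = 0.
    """
    if shape_A < 0:
        raise ValueError("shape_A must be nonnegative")
    a = np.asarray(a_linear, dtype=float)
    if shape_A == 0.0:
        return a.copy()
    return np.expm1(shape_A * a) / np.expm1(shape_A)


def activation_from_envelope(
    envelope: np.ndarray, params: ActivationParams, dt: float
) -> np.ndarray:
    """Full chain: envelope -> excitation -> dynamics -> non-linearization."""
    u = excitation_from_emg(envelope, params, dt)
    a_lin = activation_dynamics(u, params.tau_act, dt)
    return nonlinearize(a_lin, params.shape_A)


def fiber_kinematics(
    l_mt: np.ndarray, v_mt: np.ndarray, params: MuscleTendonParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid-tendon fiber kinematics.

    With the tendon fixed at slack length, the fiber spans the remaining
    length at constant muscle thickness h = l_opt * sin(alpha0):

        l_fiber = sqrt(h^2 + (l_mt - l_ts)^2)
        pennation = asin(h / l_fiber)
        v_fiber = v_mt * cos(pennation)

    Returns (fiber_length, fiber_velocity, pennation).
    """
    l_mt = np.asarray(l_mt, dtype=float)
    v_mt = np.asarray(v_mt, dtype=float)
    h = params.l_opt * np.sin(params.alpha0)
    proj = l_mt - params.l_ts
    if params.alpha0 == 0.0 and np.any(proj <= 0):
        raise ValueError(
            f"muscle {params.name}: l_mt <= tendon slack length with zero "
            "pennation gives a degenerate fiber"
        )
    fiber_length = np.sqrt(h * h + proj * proj)
    pennation = np.arcsin(np.clip(h / fiber_length, 0.0, 1.0))
    fiber_velocity = v_mt * np.cos(pennation)
    return fiber_length, fiber_velocity, pennation


def force_length_active(
    lnorm: np.ndarray, curves: CurveCoefficients = _DEFAULT_CURVES
) -> np.ndarray:
    """Gaussian-type active force-length bell; fl(1) = 1."""
    lnorm = np.asarray(lnorm, dtype=float)
    return np.exp(-(((lnorm - 1.0) / curves.fl_width) ** 2))


def force_length_passive(
    lnorm: np.ndarray, curves: CurveCoefficients = _DEFAULT_CURVES
) -> np.ndarray:
    """Exponential passive curve, zero up to optimal length, 1.0 at lnorm 1.7."""
    lnorm = np.asarray(lnorm, dtype=float)
    fp = np.expm1(np.clip(lnorm - 1.0, 0.0, None) * curves.fp_gain) / curves.fp_norm
    return fp


def force_velocity(
    vnorm: np.ndarray, curves: CurveCoefficients = _DEFAULT_CURVES
) -> np.ndarray:
    """Hill force-velocity curve on normalized fiber velocity.

    vnorm = v_fiber / (v_max * l_opt); negative is shortening.  Shortening
    branch is the Hill hyperbola with fv(0) = 1, fv(-1) = 0; the eccentric
    branch rises C1-continuously to a plateau at ``fv_ecc_max``.
    """
    v = np.asarray(vnorm, dtype=float)
    af = curves.fv_shape
    out = np.empty_like(v)
    shortening = v < 0
    vs = np.clip(v, -1.0, 0.0)
    out_s = (1.0 + vs) / (1.0 - vs / af)
    # eccentric branch: fv = fmax - (fmax - 1)/(1 + c v), c chosen for slope
    # continuity with the hyperbola at v = 0 (slope there is 1 + 1/af)
    fmax = curves.fv_ecc_max
    c = (1.0 + 1.0 / af) / (fmax - 1.0)
    out_e = fmax - (fmax - 1.0) / (1.0 + c * np.clip(v, 0.0, None))
    out = np.where(shortening, out_s, out_e)
    out[v <= -1.0] = 0.0
    return out


def muscle_force(
    a: np.ndarray,
    fiber_length: np.ndarray,
    fiber_velocity: np.ndarray,
    params: MuscleTendonParams,
    curves: CurveCoefficients = _DEFAULT_CURVES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hill-model fiber forces and tendon force.

    f_active = a * F_iso * fl * fv, f_passive = F_iso * fp (both along the
    fiber); f_total = (f_active + f_passive) * cos(pennation) along the
    tendon.  Returns (f_active, f_passive, f_total).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("activation outside [0, 1]")
    lnorm = np.asarray(fiber_length, float) / params.l_opt
    vnorm = np.asarray(fiber_velocity, float) / (params.v_max * params.l_opt)
    f_active = a * params.f_max_iso * force_length_active(lnorm, curves) * force_velocity(vnorm, curves)
    f_passive = params.f_max_iso * force_length_passive(lnorm, curves)
    h = params.l_opt * np.sin(params.alpha0)
    cos_penn = np.sqrt(1.0 - np.clip(h / np.asarray(fiber_length, float), 0.0, 1.0) ** 2)
    f_total = (f_active + f_passive) * cos_penn
    return f_active, f_passive, f_total


def force_per_unit_activation(
    l_mt: np.ndarray,
    v_mt: np.ndarray,
    params: MuscleTendonParams,
    curves: CurveCoefficients = _DEFAULT_CURVES,
) -> tuple[np.ndarray, np.ndarray]:
    """Tendon-force decomposition F_total = a * F_unit + F_pass at fixed kinematics.

    Exact for the rigid-tendon model; this affine structure is what the
    static-optimization QP exploits.  Returns (F_unit, F_pass), both N.
    """
    fl, fv, penn = fiber_kinematics(l_mt, v_mt, params)
    f_act1, f_pass, f_tot1 = muscle_force(np.ones_like(fl), fl, fv, params, curves)
    cos_penn = np.cos(penn)
    return f_act1 * cos_penn, f_pass * cos_penn
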