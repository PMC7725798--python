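"""Muscle metabolic energetics: B04, U03 and U10 models, and cost of transport.

Three published phenomenological models of muscle energy expenditure are
implemented, all functions of muscle activation/excitation, normalized
fiber length and velocity, and fiber forces:

* **B04** (Bhargava et al. 2004): activation heat, fiber-length-modulated
  maintenance heat, shortening/lengthening heat with force-dependent
  coefficients, and mechanical work rate including negative (eccentric)
  work.  Heat during lengthening is *negative*.
* **U03** (Umberger et al. 2003): combined activation+maintenance heat
  (mass-specific, scaled by fiber-type mix and an activation-dependent
  exponent), velocity-dependent shortening/lengthening heat with *positive*
  lengthening heat, and work rate including negative work.
* **U10** (Umberger 2010): the 2003 model with eccentric work *excluded*
  from the work rate.

Model coefficients are not hard-coded: they are transcribed from the cited
publications into versioned YAML configs shipped with the package
(``data/metabolic_constants/``), each annotated with its source construct.

Cost of transport integrates whole-body rate over the gait cycle:
CoT = (integral of P dt) / (body_mass * speed * t_f), in J/(kg·m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .mtu_mechanics import MuscleState, MuscleTendonParams, force_length_active

__all__ = [
    "MetabolicConstants",
    "MetabolicRateSeries",
    "load_constants",
    "muscle_mass",
    "rates_b04",
    "rates_u03",
    "rates_u10",
    "muscle_rates",
    "whole_body_rate",
    "cost_of_transport",
    "MODEL_IDS",
]

MODEL_IDS = ("B04", "U03", "U10")


@dataclass(frozen=True)
class MetabolicConstants:
    """One energetics model's coefficient block (from its YAML config)."""

    model_id: str
    specific_tension: float  # Pa
    muscle_density: float  # kg/m^3
    include_negative_work: bool
    lengthening_heat_sign: str  # {"negative", "positive"}
    basal_rate_w_per_kg_body: float
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.specific_tension <= 0:
            raise ValueError("specific tension must be positive")
        # sign/work flags are part of each model's identity
        expected = {
            "B04": ("negative", True),
            "U03": ("positive", True),
            "U10": ("positive", False),
        }
        if self.model_id in expected:
            sign, neg_work = expected[self.model_id]
            if self.lengthening_heat_sign != sign or self.include_negative_work != neg_work:
                raise ValueError(
                    f"{self.model_id}: lengthening-heat sign / negative-work flags "
                    "inconsistent with the model definition"
                )


def load_constants(model_id: str, specific_tension: float | None = None) -> MetabolicConstants:
    """Load a model's coefficient config; optionally override max muscle stress."""
    mid = model_id.upper()
    if mid not in MODEL_IDS:
        raise ValueError(f"unknown metabolic model {model_id!r}; expected one of {MODEL_IDS}")
    ref = resources.files("myocot.data.metabolic_constants") / f"{mid.lower()}.yaml"
    raw = yaml.safe_load(ref.read_text())
    return MetabolicConstants(
        model_id=raw["model_id"],
        specific_tension=float(
            specific_tension if specific_tension is not None else raw["specific_tension_pa"]
        ),
        muscle_density=float(raw["muscle_density_kg_m3"]),
        include_negative_work=bool(raw["include_negative_work"]),
        lengthening_heat_sign=str(raw["lengthening_heat_sign"]),
        basal_rate_w_per_kg_body=float(raw["basal_rate_w_per_kg_body"]),
        coefficients={k: float(v) for k, v in raw["coefficients"].items()},
    )


@dataclass
class MetabolicRateSeries:
    """Per-muscle metabolic rate components over the cycle (all W, absolute)."""

    model_id: str
    activation_heat_rate: np.ndarray
    maintenance_heat_rate: np.ndarray
    shortening_lengthening_heat_rate: np.ndarray
    work_rate: np.ndarray
    total_rate: np.ndarray

    def __post_init__(self) -> None:
        s = (
            self.activation_heat_rate
            + self.maintenance_heat_rate
            + self.shortening_lengthening_heat_rate
            + self.work_rate
        )
        if not np.allclose(s, self.total_rate, rtol=0, atol=1e-9):
            raise ValueError("total_rate must equal the sum of its components")


def muscle_mass(params: MuscleTendonParams, constants: MetabolicConstants) -> float:
    """Muscle mass from maximum isometric force, specific tension and l_opt.

    mass = density * (F_max / sigma) * l_opt; PCSA = F_max / sigma.
    """
    return (
        constants.muscle_density
        * (params.f_max_iso / constants.specific_tension)
        * params.l_opt
    )


def _b04_fiber_length_dependence(lnorm: np.ndarray) -> np.ndarray:
    """Piecewise maintenance-heat modulation by normalized fiber length."""
    lnorm = np.asarray(lnorm, float)
    out = np.zeros_like(lnorm)
    out = np.where(lnorm <= 0.5, 0.5, out)
    out = np.where((lnorm > 0.5) & (lnorm <= 1.0), lnorm, out)
    out = np.where((lnorm > 1.0) & (lnorm <= 1.5), -2.0 * lnorm + 3.0, out)
    return out


def rates_b04(
    state: MuscleState, params: MuscleTendonParams, constants: MetabolicConstants
) -> MetabolicRateSeries:
    """Bhargava et al. (2004) heat and work rates for one muscle (W)."""
    c = constants.coefficients
    m = muscle_mass(params, constants)
    u = np.clip(state.u, 0.0, 1.0)
    a = np.clip(state.a, 0.0, 1.0)
    f_st = 1.0 - params.fast_twitch_fraction
    f_ft = params.fast_twitch_fraction
    lnorm = state.fiber_length / params.l_opt
    v = state.fiber_velocity  # m/s, positive = lengthening

    act = m * c["decay_function"] * (
        c["activation_heat_slow"] * f_st * np.sin(np.pi / 2.0 * u)
        + c["activation_heat_fast"] * f_ft * (1.0 - np.cos(np.pi / 2.0 * u))
    )
    maint = m * _b04_fiber_length_dependence(lnorm) * (
        c["maintenance_heat_slow"] * f_st * np.sin(np.pi / 2.0 * a)
        + c["maintenance_heat_fast"] * f_ft * (1.0 - np.cos(np.pi / 2.0 * a))
    )
    # shortening/lengthening heat: hdot = -alpha * v_fiber
    f_ce = state.f_active
    f_ce_iso = a * params.f_max_iso * force_length_active(lnorm)
    alpha = np.where(
        v <= 0,
        c["shortening_coeff_iso"] * f_ce_iso + c["shortening_coeff_force"] * f_ce,
        c["lengthening_coeff"] * f_ce,
    )
    sl = -alpha * v
    work = -f_ce * v  # positive when shortening; eccentric work included
    total = act + maint + sl + work
    return MetabolicRateSeries("B04", act, maint, sl, work, total)


def _umberger_rates(
    state: MuscleState,
    params: MuscleTendonParams,
    constants: MetabolicConstants,
) -> MetabolicRateSeries:
    """Shared machinery of the 2003 and 2010 Umberger models."""
    c = constants.coefficients
    m = muscle_mass(params, constants)
    u = np.clip(state.u, 0.0, 1.0)
    a = np.clip(state.a, 0.0, 1.0)
    f_ft = params.fast_twitch_fraction
    lnorm = state.fiber_length / params.l_opt
    vnorm = state.fiber_velocity / params.l_opt  # l_opt/s, positive = lengthening
    s_aer = c["aerobic_scale"]

    # effective activation A(t): excitation leads during activation
    A = np.where(u > a, u, (u + a) / 2.0)
    A_am = A ** c["act_maint_exponent"]
    A_s = A ** c["shortening_exponent"]
    A_l = A ** c["lengthening_exponent"]

    # heat rates scale down above optimal length with the force-length curve
    f_iso = force_length_active(lnorm)
    long_fibers = lnorm > 1.0
    length_mod = np.where(
        long_fibers, c["length_dep_offset"] + c["length_dep_slope"] * f_iso, 1.0
    )

    h_am = (c["act_maint_heat_fast_slope"] * f_ft + c["act_maint_heat_intercept"])
    h_am = h_am * length_mod * A_am * s_aer  # W/kg

    vmax_ft = params.v_max  # l_opt/s
    vmax_st = c["vmax_slow_fraction"] * vmax_ft
    alpha_st = c["shortening_coeff_slow_numerator"] / vmax_st
    alpha_ft = c["shortening_coeff_fast_numerator"] / vmax_ft
    alpha_len = c["lengthening_coeff_factor"] * alpha_st

    shortening = vnorm <= 0
    h_s = -(alpha_st * (1.0 - f_ft) + alpha_ft * f_ft) * vnorm * A_s
    h_l = alpha_len * vnorm * A_l
    h_sl = np.where(shortening, h_s, h_l)
    h_sl = h_sl * np.where(long_fibers, f_iso, 1.0) * s_aer  # W/kg

    w = -state.f_active * state.fiber_velocity / m  # W/kg
    if not constants.include_negative_work:
        w = np.clip(w, 0.0, None)

    # activation and maintenance heat are a single combined term in the
    # Umberger formulation; reported under maintenance_heat_rate
    act = np.zeros_like(h_am)
    h_am_w, h_sl_w, w_w = m * h_am, m * h_sl, m * w
    return MetabolicRateSeries(
        constants.model_id,
        act,
        h_am_w,
        h_sl_w,
        w_w,
        act + h_am_w + h_sl_w + w_w,
    )


def rates_u03(
    state: MuscleState, params: MuscleTendonParams, constants: MetabolicConstants
) -> MetabolicRateSeries:
    """Umberger et al. (2003) rates for one muscle (W); eccentric work included."""
    if constants.model_id != "U03":
        raise ValueError("constants block is not U03")
    return _umberger_rates(state, params, constants)


def rates_u10(
    state: MuscleState, params: MuscleTendonParams, constants: MetabolicConstants
) -> MetabolicRateSeries:
    """Umberger (2010) rates for one muscle (W); eccentric work excluded."""
    if constants.model_id != "U10":
        raise ValueError("constants block is not U10")
    return _umberger_rates(state, params, constants)


def muscle_rates(
    state: MuscleState, params: MuscleTendonParams, constants: MetabolicConstants
) -> MetabolicRateSeries:
    """Dispatch on the constants block's model id."""
    return {
        "B04": rates_b04,
        "U03": rates_u03,
        "U10": rates_u10,
    }[constants.model_id](state, params, constants)


def whole_body_rate(
    per_muscle: list[MetabolicRateSeries],
    body_mass: float,
    constants: MetabolicConstants,
    include_basal: bool = True,
    clamp_muscle_totals: bool = False,
) -> np.ndarray:
    """Whole-body metabolic rate series: sum of muscles (+ basal), W.

    ``clamp_muscle_totals`` optionally floors each muscle's total at zero
    (B04 totals can dip negative during strong eccentric phases; the default
    keeps the model's sign conventions).
    """
    if not per_muscle:
        raise ValueError("no muscle rate series given")
    totals = np.sum(
        [
            np.clip(s.total_rate, 0.0, None) if clamp_muscle_totals else s.total_rate
            for s in per_muscle
        ],
        axis=0,
    )
    if include_basal:
        totals = totals + constants.basal_rate_w_per_kg_body * body_mass
    return totals


def cost_of_transport(
    rate_series: np.ndarray, body_mass: float, speed: float, t_f: float
) -> float:
    """CoT = (integral of whole-body rate over the cycle) / (mass * distance).

    Trapezoidal integration on the (101-sample) normalized cycle; J/(kg·m).
    """
    if speed <= 0 or body_mass <= 0:
        raise ValueError("speed and body_mass must be positive")
    if t_f <= 0:
        raise ValueError("t_f must be positive")
    rate = np.asarray(rate_series, float)
    t = np.linspace(0.0, t_f, rate.shape[0])
    energy = float(np.trapezoid(rate, t))
    return energy / (body_mass * speed * t_f)
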