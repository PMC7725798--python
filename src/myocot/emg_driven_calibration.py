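"""EMG-driven model calibration: match inverse-dynamics joint moments.

Calibration adjusts EMG-to-activation parameters (electromechanical delay,
activation time constant, non-linearization shape factor, EMG scale
factor), Hill-model parameters (optimal fiber length and tendon slack
length, as bounded multipliers of their initial values), and optionally a
geometry offset, so that the net joint moments predicted from the
subject's EMG best match the inverse-dynamics moments across all
calibration trials.  Quadratic penalty terms discourage divergence from
the initial parameter values, and a passive term keeps the model's
passive joint moments near published reference curves.

The cost is a sum of squares, so the optimizer is a bound-constrained
nonlinear least-squares method (scipy's trust-region reflective).
All design variables are dimensionless: multiplicative parameters are
optimized as multipliers of their initial values; parameters whose
initial value may be zero (delay, shape factor) are optimized as absolute
values divided by a fixed class scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import LegModel
from .motion_io import GaitTrial, MotionTable
from .mtu_mechanics import (
    ActivationParams,
    MuscleTendonParams,
    activation_from_envelope,
    fiber_kinematics,
    force_per_unit_activation,
    muscle_force,
)
from .static_optimization import _cycle_gradient

__all__ = [
    "ParameterClass",
    "CalibrationProblem",
    "CalibrationResult",
    "predicted_moments",
    "calibration_cost",
    "calibrate",
    "activation_rmse",
]

# class name -> (kind, scale, lo, hi); "mult" variables are multipliers of the
# initial value, "abs" variables are value/scale
PARAM_CLASSES: dict[str, tuple[str, float, float, float]] = {
    "emd": ("abs", 0.05, 0.0, 2.0),  # seconds/0.05 -> emd in [0, 0.1]
    "tau_act": ("mult", 1.0, 0.5, 2.0),
    "shape_A": ("abs", 3.0, 0.0, 1.0),  # A in [0, 3]
    "emg_scale": ("mult", 1.0, 0.2, 1.5),
    "l_opt": ("mult", 1.0, 0.75, 1.25),
    "l_ts": ("mult", 1.0, 0.75, 1.25),
    "geom_offset": ("abs", 0.01, -2.0, 2.0),  # meters/0.01 -> +/- 2 cm
}

DEFAULT_ADJUSTABLE = ("emd", "tau_act", "emg_scale", "l_opt", "l_ts")


@dataclass
class PassiveReference:
    """Published passive joint moment curve for one DOF: angle -> N·m."""

    dof: str
    angles: np.ndarray  # rad
    moments: np.ndarray  # N·m


@dataclass
class CalibrationProblem:
    trials: list[GaitTrial]
    model: LegModel  # initial (uncalibrated) model
    adjustable: tuple[str, ...] = DEFAULT_ADJUSTABLE
    penalty_weights: dict[str, float] = field(default_factory=dict)
    passive_reference: list[PassiveReference] = field(default_factory=list)
    passive_weight: float = 1.0
    default_penalty: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.adjustable) - set(PARAM_CLASSES)
        if unknown:
            raise ValueError(f"unknown parameter classes {sorted(unknown)}")
        if not self.trials:
            raise ValueError("at least one calibration trial is required")

    def penalty(self, cls: str) -> float:
        return self.penalty_weights.get(cls, self.default_penalty)

    # --- design-vector encoding ------------------------------------------
    def x0(self) -> np.ndarray:
        x = []
        for name in self.model.muscle_names:
            for cls in self.adjustable:
                kind, scale, _, _ = PARAM_CLASSES[cls]
                p0 = _get_param(self.model, name, cls)
                x.append(1.0 if kind == "mult" else p0 / scale)
        return np.asarray(x)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for _ in self.model.muscle_names:
            for cls in self.adjustable:
                _, _, l, h = PARAM_CLASSES[cls]
                lo.append(l)
                hi.append(h)
        return np.asarray(lo), np.asarray(hi)

    def apply(self, x: np.ndarray) -> LegModel:
        """Model with design vector ``x`` applied (initial model untouched)."""
        lo, hi = self.bounds()
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError("design vector outside declared bounds")
        model = self.model.copy()
        k = 0
        for name in self.model.muscle_names:
            updates: dict[str, float] = {}
            for cls in self.adjustable:
                kind, scale, _, _ = PARAM_CLASSES[cls]
                p0 = _get_param(self.model, name, cls)
                updates[cls] = x[k] * p0 if kind == "mult" else x[k] * scale
                k += 1
            _set_params(model, name, updates)
        return model


def _get_param(model: LegModel, muscle: str, cls: str) -> float:
    act, mtp = model.activation[muscle], model.muscles[muscle]
    if cls in ("emd", "tau_act", "shape_A", "emg_scale"):
        return getattr(act, cls)
    if cls in ("l_opt", "l_ts"):
        return getattr(mtp, cls)
    if cls == "geom_offset":
        return 0.0
    raise KeyError(cls)


def _set_params(model: LegModel, muscle: str, updates: dict[str, float]) -> None:
    act = model.activation[muscle]
    mtp = model.muscles[muscle]
    act_kw = {
        "emd": act.emd,
        "tau_act": act.tau_act,
        "shape_A": act.shape_A,
        "emg_scale": act.emg_scale,
    }
    mtp_kw = {
        "name": mtp.name,
        "f_max_iso": mtp.f_max_iso,
        "l_opt": mtp.l_opt,
        "l_ts": mtp.l_ts,
        "alpha0": mtp.alpha0,
        "v_max": mtp.v_max,
        "fast_twitch_fraction": mtp.fast_twitch_fraction,
    }
    for cls, val in updates.items():
        if cls in act_kw:
            act_kw[cls] = float(np.clip(val, *_hard_range(cls)))
        elif cls in ("l_opt", "l_ts"):
            mtp_kw[cls] = val
        elif cls == "geom_offset":
            surr = model.surrogates[muscle]
            surr.coefficients = surr.coefficients.copy()
            surr.coefficients[0] += val  # constant monomial is first
    model.activation[muscle] = ActivationParams(**act_kw)
    model.muscles[muscle] = MuscleTendonParams(**mtp_kw)


def _hard_range(cls: str) -> tuple[float, float]:
    return {
        "emd": (0.0, 0.1),
        "tau_act": (0.01, 0.1),
        "shape_A": (0.0, 3.0),
        "emg_scale": (1e-6, 1.5),
    }[cls]


@dataclass
class CalibrationResult:
    model: LegModel
    x: np.ndarray
    cost_initial: float
    cost_final: float
    cost_terms: dict[str, float]  # moment / passive / penalty decomposition
    cost_history: list[float]
    moment_rmse: dict[str, float]  # per DOF, pooled over trials, N·m
    passive_rmse: float
    converged: bool


def predicted_moments(model: LegModel, trial: GaitTrial) -> MotionTable:
    """Net joint moments from the EMG-driven chain.

    moment_j(t) = sum_muscles r_j(q(t)) * f_total(t), with activations from
    each muscle's mapped EMG envelope through the excitation/activation
    chain and forces from the rigid-tendon Hill model.
    """
    dofs = model.dof_names
    q = np.column_stack([trial.angles.column(d) for d in dofs])
    qdot = _cycle_gradient(q, trial.angles.time)
    dt = trial.angles.time[1] - trial.angles.time[0]
    moments = np.zeros((q.shape[0], len(dofs)))
    for name in model.muscle_names:
        channel = model.emg_map.get(name)
        if channel is None:
            raise KeyError(f"muscle {name!r} has no EMG channel mapping")
        envelope = trial.emg.column(channel)
        a = activation_from_envelope(envelope, model.activation[name], dt)
        l_mt, v_mt, r = model.geometry(name, q, qdot, dofs)
        fl, fv, _ = fiber_kinematics(l_mt, v_mt, model.muscles[name])
        _, _, f_tot = muscle_force(a, fl, fv, model.muscles[name], model.curves)
        moments += r * f_tot[:, None]
    return MotionTable(dofs, trial.angles.time, moments)


def _passive_model_moments(model: LegModel, ref: PassiveReference) -> np.ndarray:
    """Model passive moments about one DOF over a reference angle grid.

    Other DOFs held at neutral (0 rad), zero velocity, zero activation.
    """
    dofs = model.dof_names
    j = dofs.index(ref.dof)
    q = np.zeros((len(ref.angles), len(dofs)))
    q[:, j] = ref.angles
    qdot = np.zeros_like(q)
    out = np.zeros(len(ref.angles))
    for name in model.muscle_names:
        l_mt, v_mt, r = model.geometry(name, q, qdot, dofs)
        fu, fp = force_per_unit_activation(l_mt, v_mt, model.muscles[name], model.curves)
        out += r[:, j] * fp
    return out


def _residuals(x: np.ndarray, problem: CalibrationProblem) -> np.ndarray:
    model = problem.apply(x)
    res = []
    for trial in problem.trials:
        pred = predicted_moments(model, trial)
        for d in model.dof_names:
            res.append(pred.column(d) - trial.moments.column(d))
    for ref in problem.passive_reference:
        res.append(
            np.sqrt(problem.passive_weight)
            * (_passive_model_moments(model, ref) - ref.moments)
        )
    x0 = problem.x0()
    k = 0
    for _ in problem.model.muscle_names:
        for cls in problem.adjustable:
            w = problem.penalty(cls)
            res.append(np.atleast_1d(np.sqrt(w) * (x[k] - x0[k])))
            k += 1
    return np.concatenate(res)


def calibration_cost(
    x: np.ndarray, problem: CalibrationProblem
) -> tuple[float, dict[str, float]]:
    """Total sum-of-squares cost and its exact decomposition.

    total = moment term + passive term + penalty term; the three terms are
    returned separately and sum to the total exactly.
    """
    model = problem.apply(x)
    moment = 0.0
    for trial in problem.trials:
        pred = predicted_moments(model, trial)
        for d in model.dof_names:
            moment += float(np.sum((pred.column(d) - trial.moments.column(d)) ** 2))
    passive = 0.0
    for ref in problem.passive_reference:
        passive += problem.passive_weight * float(
            np.sum((_passive_model_moments(model, ref) - ref.moments) ** 2)
        )
    x0 = problem.x0()
    penalty = 0.0
    k = 0
    for _ in problem.model.muscle_names:
        for cls in problem.adjustable:
            penalty += problem.penalty(cls) * float((x[k] - x0[k]) ** 2)
            k += 1
    return moment + passive + penalty, {
        "moment": moment,
        "passive": passive,
        "penalty": penalty,
    }


def calibrate(
    problem: CalibrationProblem,
    max_iter: int = 100,
    tol: float = 1e-10,
    verbose: bool = False,
) -> CalibrationResult:
    """Bound-constrained nonlinear least-squares calibration.

    Deterministic (no randomness); cost is non-increasing across accepted
    trust-region iterates, so the final cost never exceeds the initial one.
    """
    x0 = problem.x0()
    lo, hi = problem.bounds()
    c0, _ = calibration_cost(x0, problem)
    if not np.isfinite(c0):
        raise ArithmeticError("non-finite calibration cost at the initial point")
    history: list[float] = [c0]

    def fun(x):
        r = _residuals(x, problem)
        history.append(float(np.dot(r, r)))
        return r

    res = least_squares(
        fun,
        x0,
        bounds=(lo, hi),
        method="trf",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter,
        x_scale="jac",
        verbose=2 if verbose else 0,
    )
    c_final, terms = calibration_cost(res.x, problem)
    model = problem.apply(res.x)

    sq_err = {d: [] for d in model.dof_names}
    for trial in problem.trials:
        pred = predicted_moments(model, trial)
        for d in model.dof_names:
            sq_err[d].append((pred.column(d) - trial.moments.column(d)) ** 2)
    moment_rmse = {
        d: float(np.sqrt(np.mean(np.concatenate(v)))) for d, v in sq_err.items()
    }
    if problem.passive_reference:
        p_sq = np.concatenate(
            [
                (_passive_model_moments(model, ref) - ref.moments) ** 2
                for ref in problem.passive_reference
            ]
        )
        passive_rmse = float(np.sqrt(np.mean(p_sq)))
    else:
        passive_rmse = 0.0
    return CalibrationResult(
        model=model,
        x=res.x,
        cost_initial=c0,
        cost_final=c_final,
        cost_terms=terms,
        cost_history=history,
        moment_rmse=moment_rmse,
        passive_rmse=passive_rmse,
        converged=bool(res.success),
    )


def activation_rmse(
    a_ref: dict[str, np.ndarray], a_test: dict[str, np.ndarray]
) -> tuple[dict[str, float], float, float]:
    """Per-muscle RMSE between two activation series sets, plus mean and SD.

    Both sets must cover the same muscles on the same (101-sample) time base.
    """
    if set(a_ref) != set(a_test):
        raise ValueError("muscle sets differ between the two activation sets")
    per = {}
    for name in a_ref:
        r, t = np.asarray(a_ref[name], float), np.asarray(a_test[name], float)
        if r.shape != t.shape:
            raise ValueError(f"series shapes differ for muscle {name!r}")
        per[name] = float(np.sqrt(np.mean((r - t) ** 2)))
    vals = np.array(list(per.values()))
    return per, float(np.mean(vals)), float(np.std(vals))
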