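"""Per-frame static optimization of the muscle redundancy problem.

Each frame solves the quadratic program

    min_a  sum_i a_i^2 + w_r * sum_j r_j^2
    s.t.   sum_i r_ij (a_i F_unit_i + F_pass_i) + r_j = M_j   for each DOF j
           0 <= a_i <= 1

where F_unit_i is muscle i's tendon force per unit activation at the
frame's kinematics (exact under the rigid-tendon model), F_pass_i its
passive tendon force, r_ij the moment arm, M_j the inverse-dynamics moment,
and r_j a reserve moment with heavy quadratic penalty w_r that guarantees
feasibility (e.g. when the demanded moment exceeds total muscle capacity).

Eliminating the reserves turns the QP into a bound-constrained linear
least-squares problem, which is solved exactly by an active-set method
(``scipy.optimize.lsq_linear`` with BVLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .model import LegModel
from .motion_io import GaitTrial, MotionTable
from .mtu_mechanics import force_per_unit_activation

__all__ = ["FrameProblem", "ActivationSolution", "solve_frame", "solve_trial"]

RESERVE_FREE_TOL = 1e-3  # N·m: reserves below this count as "not needed"


@dataclass
class FrameProblem:
    """One frame of the redundancy problem."""

    f_unit: np.ndarray  # (n_muscles,), N per unit activation, >= 0
    f_passive: np.ndarray  # (n_muscles,), N
    moment_arms: np.ndarray  # (n_muscles, n_dofs), m
    target_moments: np.ndarray  # (n_dofs,), N·m
    reserve_weight: float = 1000.0

    def __post_init__(self) -> None:
        self.f_unit = np.asarray(self.f_unit, float)
        self.f_passive = np.asarray(self.f_passive, float)
        self.moment_arms = np.atleast_2d(np.asarray(self.moment_arms, float))
        self.target_moments = np.atleast_1d(np.asarray(self.target_moments, float))
        n_m, n_d = self.moment_arms.shape
        if self.f_unit.shape != (n_m,) or self.f_passive.shape != (n_m,):
            raise ValueError("muscle force vectors inconsistent with moment arms")
        if self.target_moments.shape != (n_d,):
            raise ValueError("target moments inconsistent with moment arms")
        if np.any(self.f_unit < 0):
            raise ValueError("force per unit activation must be nonnegative")
        if self.reserve_weight <= 0:
            raise ValueError("reserve_weight must be positive")


@dataclass
class ActivationSolution:
    activations: np.ndarray  # in [0, 1]
    reserve_moments: np.ndarray  # N·m per DOF
    objective: float
    feasible_without_reserves: bool


def solve_frame(problem: FrameProblem) -> ActivationSolution:
    """Solve one frame's QP exactly.

    With r_j := M_j - sum_i r_ij (a_i F_unit_i + F_pass_i), the objective
    ||a||^2 + w ||r(a)||^2 is a linear least-squares functional of a with
    box bounds; BVLS returns the exact KKT point.
    """
    B = problem.moment_arms.T * problem.f_unit  # (n_dofs, n_muscles)
    m_target = problem.target_moments - problem.moment_arms.T @ problem.f_passive
    n_m = problem.f_unit.shape[0]
    sw = np.sqrt(problem.reserve_weight)
    A = np.vstack([np.eye(n_m), sw * B])
    b = np.concatenate([np.zeros(n_m), sw * m_target])
    res = lsq_linear(A, b, bounds=(0.0, 1.0), method="bvls", tol=1e-14)
    a = np.clip(res.x, 0.0, 1.0)
    reserves = m_target - B @ a
    objective = float(np.sum(a**2) + problem.reserve_weight * np.sum(reserves**2))
    return ActivationSolution(
        activations=a,
        reserve_moments=reserves,
        objective=objective,
        feasible_without_reserves=bool(np.max(np.abs(reserves), initial=0.0) <= RESERVE_FREE_TOL),
    )


def solve_trial(
    trial: GaitTrial,
    model: LegModel,
    reserve_weight: float = 1000.0,
    include_passive: bool = True,
) -> tuple[MotionTable, dict]:
    """Frame-by-frame static optimization over one normalized gait cycle.

    Returns the activation table (one column per muscle, 101 frames) and a
    diagnostics dict with per-DOF reserve-moment RMS and the per-frame
    objective.  ``include_passive`` controls whether passive muscle forces
    enter the moment constraint.
    """
    dofs = model.dof_names
    q = np.column_stack([trial.angles.column(d) for d in dofs])
    qdot = _cycle_gradient(q, trial.angles.time)
    m_target = np.column_stack([trial.moments.column(d) for d in dofs])
    n_frames = q.shape[0]
    names = model.muscle_names

    f_unit = np.empty((n_frames, len(names)))
    f_pass = np.empty((n_frames, len(names)))
    arms = np.empty((n_frames, len(names), len(dofs)))
    for i, name in enumerate(names):
        l_mt, v_mt, r = model.geometry(name, q, qdot, dofs)
        fu, fp = force_per_unit_activation(l_mt, v_mt, model.muscles[name], model.curves)
        f_unit[:, i] = fu
        f_pass[:, i] = fp if include_passive else 0.0
        arms[:, i, :] = r

    activations = np.empty((n_frames, len(names)))
    reserves = np.empty((n_frames, len(dofs)))
    objectives = np.empty(n_frames)
    for k in range(n_frames):
        sol = solve_frame(
            FrameProblem(
                f_unit=np.clip(f_unit[k], 0.0, None),
                f_passive=f_pass[k],
                moment_arms=arms[k],
                target_moments=m_target[k],
                reserve_weight=reserve_weight,
            )
        )
        if not np.all(np.isfinite(sol.activations)):
            raise ArithmeticError(f"static optimization failed at frame {k}")
        activations[k] = sol.activations
        reserves[k] = sol.reserve_moments
        objectives[k] = sol.objective

    table = MotionTable(names, trial.angles.time, activations)
    diagnostics = {
        "reserve_rms_per_dof": {
            d: float(np.sqrt(np.mean(reserves[:, j] ** 2))) for j, d in enumerate(dofs)
        },
        "objective_mean": float(np.mean(objectives)),
        "frames_needing_reserves": int(
            np.sum(np.max(np.abs(reserves), axis=1) > RESERVE_FREE_TOL)
        ),
    }
    return table, diagnostics


def _cycle_gradient(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Time derivative of a periodic, cycle-normalized trajectory.

    Central differences with cyclic wrap (frame 0 and frame -1 are the same
    gait event), so endpoint derivatives do not suffer one-sided bias.
    """
    q = np.atleast_2d(q)
    n = q.shape[0]
    dt = t[1] - t[0]
    qdot = np.empty_like(q)
    # interior: standard central difference
    qdot[1:-1] = (q[2:] - q[:-2]) / (2 * dt)
    # cyclic closure: sample n-1 repeats sample 0, so wrap skips it
    qdot[0] = (q[1] - q[-2]) / (2 * dt)
    qdot[-1] = qdot[0]
    return qdot
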