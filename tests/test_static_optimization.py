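"""Static-optimization QP: closed forms, enumeration oracle, trial solves."""

import itertools

import numpy as np
import pytest

from myocot.model import LegModel
from myocot.motion_io import GaitEvents, GaitTrial, MotionTable
from myocot.mtu_mechanics import ActivationParams, MuscleTendonParams
from myocot.static_optimization import FrameProblem, solve_frame, solve_trial
from myocot.surrogate_geometry import SurrogatePolynomial


def qp_objective(problem: FrameProblem, a: np.ndarray) -> float:
    B = problem.moment_arms.T * problem.f_unit
    r = problem.target_moments - problem.moment_arms.T @ problem.f_passive - B @ a
    return float(np.sum(a**2) + problem.reserve_weight * np.sum(r**2))


def enumerate_qp(problem: FrameProblem) -> np.ndarray:
    """Dense active-set enumeration oracle for tiny instances.

    For every assignment of each activation to {lower bound, upper bound,
    free}, solve the unconstrained quadratic in the free coordinates and
    keep the best feasible candidate.  Exact for convex box QPs.
    """
    n = problem.f_unit.shape[0]
    B = problem.moment_arms.T * problem.f_unit
    m_t = problem.target_moments - problem.moment_arms.T @ problem.f_passive
    w = problem.reserve_weight
    # objective: a'a + w (m - B a)'(m - B a); gradient: 2a - 2w B'(m - B a)
    H = 2 * (np.eye(n) + w * B.T @ B)
    g = -2 * w * B.T @ m_t  # objective = 0.5 a'H a + g'a + const
    best, best_obj = None, np.inf
    for assignment in itertools.product([0, 1, 2], repeat=n):
        a = np.zeros(n)
        free = [i for i, s in enumerate(assignment) if s == 2]
        a[[i for i, s in enumerate(assignment) if s == 1]] = 1.0
        if free:
            Hff = H[np.ix_(free, free)]
            fixed = [i for i, s in enumerate(assignment) if s != 2]
            rhs = -(g[free] + H[np.ix_(free, fixed)] @ a[fixed]) if fixed else -g[free]
            try:
                a[free] = np.linalg.solve(Hff, rhs)
            except np.linalg.LinAlgError:
                continue
        if np.any(a < -1e-10) or np.any(a > 1 + 1e-10):
            continue
        obj = qp_objective(problem, np.clip(a, 0, 1))
        if obj < best_obj:
            best_obj, best = obj, np.clip(a, 0, 1)
    return best


class TestSolveFrame:
    def test_single_muscle_closed_form(self):
        # a = M / (r * F_unit) = 25 / (0.05 * 1000) = 0.5
        sol = solve_frame(FrameProblem([1000.0], [0.0], [[0.05]], [25.0]))
        assert sol.activations[0] == pytest.approx(0.5, abs=1e-4)
        assert abs(sol.reserve_moments[0]) < 1e-3
        assert sol.feasible_without_reserves

    def test_identical_muscles_share_load_equally(self):
        sol = solve_frame(
            FrameProblem([800.0, 800.0], [0.0, 0.0], [[0.05], [0.05]], [30.0])
        )
        assert sol.activations[0] == pytest.approx(sol.activations[1], abs=1e-10)

    def test_saturation_and_reserve_takeover(self):
        sol = solve_frame(FrameProblem([1000.0], [0.0], [[0.05]], [100.0]))
        assert sol.activations[0] == pytest.approx(1.0, abs=1e-9)
        assert sol.reserve_moments[0] == pytest.approx(50.0, abs=1e-6)
        assert not sol.feasible_without_reserves

    def test_passive_force_enters_constraint(self):
        # passive force already supplies 0.05*200 = 10 N·m of the 25 target
        sol = solve_frame(FrameProblem([1000.0], [200.0], [[0.05]], [25.0]))
        assert sol.activations[0] == pytest.approx(0.3, abs=1e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_active_set_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_m, n_d = 3, 2
        problem = FrameProblem(
            f_unit=rng.uniform(200, 2000, n_m),
            f_passive=rng.uniform(0, 50, n_m),
            moment_arms=rng.uniform(-0.06, 0.06, (n_m, n_d)),
            target_moments=rng.uniform(-40, 40, n_d),
            reserve_weight=1000.0,
        )
        sol = solve_frame(problem)
        oracle = enumerate_qp(problem)
        assert qp_objective(problem, sol.activations) == pytest.approx(
            qp_objective(problem, oracle), rel=1e-6, abs=1e-9
        )
        np.testing.assert_allclose(sol.activations, oracle, atol=1e-5)

    @pytest.mark.parametrize("seed", range(4))
    def test_beats_random_feasible_points(self, seed):
        rng = np.random.default_rng(100 + seed)
        problem = FrameProblem(
            f_unit=rng.uniform(200, 2000, 5),
            f_passive=np.zeros(5),
            moment_arms=rng.uniform(-0.06, 0.06, (5, 2)),
            target_moments=rng.uniform(-30, 30, 2),
        )
        sol = solve_frame(problem)
        opt = qp_objective(problem, sol.activations)
        for a in rng.random((1000, 5)):
            assert qp_objective(problem, a) >= opt - 1e-9

    def test_huge_reserve_weight_drives_reserves_to_zero(self):
        sol = solve_frame(
            FrameProblem([1000.0, 600.0], [0.0, 0.0], [[0.05], [0.04]], [20.0], reserve_weight=1e8)
        )
        assert np.max(np.abs(sol.reserve_moments)) <= 1e-4

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FrameProblem([1000.0], [0.0, 0.0], [[0.05]], [25.0])


def _one_muscle_per_dof_model() -> LegModel:
    """Non-redundant square system: QP optimum equals the generating truth."""
    dofs = ["hip_flexion"]
    m = MuscleTendonParams("solo", 2000.0, 0.1, 0.2, alpha0=0.0)
    surr = SurrogatePolynomial("solo", dofs, 1, np.array([0.3, -0.05]))
    return LegModel(
        dof_names=dofs,
        muscles={"solo": m},
        activation={"solo": ActivationParams()},
        surrogates={"solo": surr},
        emg_map={"solo": "emg_solo"},
    )


def _trial_from_model(model: LegModel, activations: np.ndarray) -> GaitTrial:
    from myocot.emg_driven_calibration import predicted_moments

    n = 101
    t_f = 1.2
    t = np.linspace(0, t_f, n)
    q = 0.3 * np.sin(2 * np.pi * t / t_f)[:, None]
    angles = MotionTable(model.dof_names, t, q)
    emg = MotionTable(["emg_solo"], t, activations[:, None])
    ev = GaitEvents(0.0, 0.7, 0.6, 0.1, t_f)
    trial = GaitTrial(
        subject_id="s",
        side_paretic="right",
        speed=0.5,
        body_mass=75.0,
        fugl_meyer=30,
        t_f=t_f,
        angles=angles,
        moments=MotionTable(model.dof_names, t, np.zeros((n, 1))),
        grf=MotionTable(["grf_right_vy"], t, np.zeros((n, 1))),
        emg=emg,
        pelvis_pos=np.zeros(n),
        foot_pos_L=np.zeros(n),
        foot_pos_R=np.zeros(n),
        events=ev,
    )
    trial.moments = predicted_moments(model, trial)
    return trial


class TestSolveTrial:
    def test_nonredundant_system_recovers_truth_activations(self):
        model = _one_muscle_per_dof_model()
        tau = np.arange(101) / 100
        a_true = 0.3 + 0.25 * np.sin(2 * np.pi * tau) ** 2
        trial = _trial_from_model(model, a_true)
        # subtract passive contribution: target activation reproduces total
        table, diag = solve_trial(trial, model)
        a_chain = __import__("myocot.pipeline", fromlist=["x"])._emg_driven_activations(
            model, trial
        )["solo"]
        np.testing.assert_allclose(table.column("solo"), a_chain, atol=1e-5)

    def test_zero_moments_zero_passive_gives_zero_activations(self):
        model = _one_muscle_per_dof_model()
        trial = _trial_from_model(model, np.zeros(101))
        trial.moments = MotionTable(
            model.dof_names, trial.angles.time, np.zeros((101, 1))
        )
        table, _ = solve_trial(trial, model, include_passive=False)
        np.testing.assert_allclose(table.values, 0.0, atol=1e-6)

    def test_redundant_leg_objective_not_worse_than_truth(self, symmetric_trial):
        trial, truth = symmetric_trial
        table, diag = solve_trial(trial, truth.model)
        names = truth.model.muscle_names
        so = np.column_stack([table.column(n) for n in names])
        gen = np.column_stack([truth.activations[n] for n in names])
        assert np.sum(so**2) <= np.sum(gen**2) + 1e-6
        assert np.all(table.values >= 0.0) and np.all(table.values <= 1.0)
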