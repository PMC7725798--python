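"""Leg-model container: muscles, activation parameters, geometry, EMG mapping.

A :class:`LegModel` bundles everything needed to turn one leg's joint
kinematics and EMG into muscle forces and net joint moments: the Hill-model
parameters of each muscle-tendon actuator, its EMG-to-activation
parameters, its polynomial geometry surrogate, and the mapping from muscle
to EMG channel.  The three analysis approaches differ only in which
parameter set they carry (generic vs calibrated) and in how activations
are produced (static optimization vs EMG-driven), so one container serves
all of them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .mtu_mechanics import (
    ActivationParams,
    CurveCoefficients,
    MuscleState,
    MuscleTendonParams,
    activation_from_envelope,
    fiber_kinematics,
    force_per_unit_activation,
    muscle_force,
)
from .surrogate_geometry import SurrogatePolynomial

__all__ = ["LegModel", "muscle_states_from_activations"]


@dataclass
class LegModel:
    """One leg's complete muscle model."""

    dof_names: list[str]
    muscles: dict[str, MuscleTendonParams]
    activation: dict[str, ActivationParams]
    surrogates: dict[str, SurrogatePolynomial]
    emg_map: dict[str, str]  # muscle -> EMG channel label
    curves: CurveCoefficients = field(default_factory=CurveCoefficients)

    def __post_init__(self) -> None:
        for name in self.muscles:
            if name not in self.surrogates:
                raise ValueError(f"muscle {name!r} has no geometry surrogate")
            if name not in self.activation:
                raise ValueError(f"muscle {name!r} has no activation parameters")

    @property
    def muscle_names(self) -> list[str]:
        return list(self.muscles)

    def copy(self) -> "LegModel":
        return copy.deepcopy(self)

    def geometry(
        self, name: str, q: np.ndarray, qdot: np.ndarray, dof_names: list[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(l_mt, v_mt, moment_arms over *all* model DOFs) for one muscle.

        ``q``/``qdot`` are (frames x n_dofs) over ``dof_names``; columns are
        mapped onto the muscle's spanned DOFs, and moment arms are scattered
        back into full-width columns (zero for unspanned DOFs).
        """
        surr = self.surrogates[name]
        idx = [dof_names.index(d) for d in surr.spanned_dofs]
        q2 = np.atleast_2d(q)[:, idx]
        qd2 = np.atleast_2d(qdot)[:, idx]
        l_mt, v_mt, r_span = surr.evaluate(q2, qd2)
        r_full = np.zeros((q2.shape[0], len(dof_names)))
        r_full[:, idx] = r_span
        return l_mt, v_mt, r_full


def muscle_states_from_activations(
    model: LegModel,
    name: str,
    a: np.ndarray,
    u: np.ndarray,
    q: np.ndarray,
    qdot: np.ndarray,
    dof_names: list[str],
) -> MuscleState:
    """Assemble the full mechanical state series of one muscle."""
    params = model.muscles[name]
    l_mt, v_mt, _ = model.geometry(name, q, qdot, dof_names)
    fl, fv, _penn = fiber_kinematics(l_mt, v_mt, params)
    f_act, f_pass, f_tot = muscle_force(a, fl, fv, params, model.curves)
    return MuscleState(
        a=np.asarray(a, float),
        u=np.asarray(u, float),
        l_mt=l_mt,
        v_mt=v_mt,
        fiber_length=fl,
        fiber_velocity=fv,
        f_active=f_act,
        f_passive=f_pass,
        f_total=f_tot,
    )
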