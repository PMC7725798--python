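"""Spatiotemporal gait asymmetry outcomes for hemiparetic walking.

Three asymmetries between the paretic and non-paretic legs, each the
absolute difference of the non-paretic and paretic values:

* step length: fore-aft foot-to-pelvis distance at each leg's heel strike;
* stance time: heel strike to toe-off duration per leg;
* double support time: paretic heel strike -> non-paretic toe-off vs
  non-paretic heel strike -> paretic toe-off.

Durations are cyclic (modulo the cycle period), so event ordering across
the cycle wrap is handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion_io import GaitEvents, GaitTrial, cyclic_duration

__all__ = [
    "AsymmetryRecord",
    "step_length_asym",
    "stance_time_asym",
    "double_support_asym",
    "trial_asymmetries",
]


@dataclass
class AsymmetryRecord:
    trial_id: str
    speed: float  # m/s
    step_length_asym: float  # m
    stance_time_asym: float  # s
    double_support_asym: float  # s
    cot: dict = None  # (approach, model) -> J/(kg·m), filled by the pipeline

    def __post_init__(self) -> None:
        for f in ("step_length_asym", "stance_time_asym", "double_support_asym"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative (absolute value)")
        if self.cot is None:
            self.cot = {}


def _value_at(time: np.ndarray, series: np.ndarray, t: float, t_f: float) -> float:
    """Series value at cyclic time t (linear interpolation, periodic wrap)."""
    tt = t % t_f
    return float(np.interp(tt, time, series))


def step_length_asym(trial: GaitTrial) -> float:
    """|d_np - d_p|: fore-aft foot-to-pelvis distance at each heel strike."""
    ev = trial.events
    t, t_f = trial.angles.time, trial.t_f
    d_np = _value_at(t, trial.foot_pos_nonparetic, ev.hs_nonparetic, t_f) - _value_at(
        t, trial.pelvis_pos, ev.hs_nonparetic, t_f
    )
    d_p = _value_at(t, trial.foot_pos_paretic, ev.hs_paretic, t_f) - _value_at(
        t, trial.pelvis_pos, ev.hs_paretic, t_f
    )
    return abs(d_np - d_p)


def stance_time_asym(events: GaitEvents, t_f: float | None = None) -> float:
    """|stance_np - stance_p|, stance = cyclic heel strike -> toe-off duration."""
    t_f = events.t_f if t_f is None else t_f
    st_p = cyclic_duration(events.hs_paretic, events.to_paretic, t_f)
    st_np = cyclic_duration(events.hs_nonparetic, events.to_nonparetic, t_f)
    return abs(st_np - st_p)


def double_support_asym(events: GaitEvents, t_f: float | None = None) -> float:
    """|DS1 - DS2| with DS1 = paretic HS -> non-paretic TO, DS2 the mirror."""
    t_f = events.t_f if t_f is None else t_f
    ds1 = cyclic_duration(events.hs_paretic, events.to_nonparetic, t_f)
    ds2 = cyclic_duration(events.hs_nonparetic, events.to_paretic, t_f)
    return abs(ds1 - ds2)


def trial_asymmetries(trial: GaitTrial, trial_id: str | None = None) -> AsymmetryRecord:
    """All three asymmetries of one trial in a single record."""
    return AsymmetryRecord(
        trial_id=trial_id or trial.subject_id,
        speed=trial.speed,
        step_length_asym=step_length_asym(trial),
        stance_time_asym=stance_time_asym(trial.events, trial.t_f),
        double_support_asym=double_support_asym(trial.events, trial.t_f),
    )
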