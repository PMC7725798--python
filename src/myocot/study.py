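"""Default study conditions: two synthetic hemiparetic subjects + references.

The deposited experimental data this pipeline was designed around are not
redistributable, so the shipped study conditions are synthetic analogs
with known ground truth:

* a *high-functioning* subject (Fugl-Meyer 32, treadmill speeds 0.4-0.8
  m/s in 0.1 m/s steps, moderate asymmetries, lower activation levels);
* a *low-functioning* subject (Fugl-Meyer 25, speeds 0.35-0.65 m/s,
  larger asymmetries, higher activation levels and hence higher CoT).

Reference "experimental" trend points emulate a published post-stroke
treadmill dataset: cost of transport falls with walking speed, rises with
step-length / stance-time / double-support asymmetry, and falls with
Fugl-Meyer score.  They are generated (synthetic, seeded), not digitized
from any publication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import ExperimentConfig, SubjectData, generic_model_from
from .synthetic_gait import (
    GroundTruth,
    SyntheticCohortSpec,
    SyntheticLegSpec,
    default_leg_spec,
    generate_cohort,
)

__all__ = [
    "high_functioning_cohort",
    "low_functioning_cohort",
    "make_reference_trends",
    "make_reference_fm",
    "build_subject",
    "default_experiment",
]

# the linear CoT-vs-speed trend (slope J/(kg·m) per m/s, intercept) each
# synthetic subject realizes under the B04 energetics model
HIGH_FN_TREND = (-3.0, 6.2)
LOW_FN_TREND = (-3.0, 7.0)


def high_functioning_cohort(seed: int = 0, trials_per_speed: int = 2) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(
        subject_id="synthHF",
        speeds=(0.4, 0.5, 0.6, 0.7, 0.8),
        trials_per_speed=trials_per_speed,
        body_mass=75.0,
        fugl_meyer=32,
        step_asym_base=0.05,
        stance_asym_base=0.08,
        ds_asym_base=0.05,
        cot_trend=HIGH_FN_TREND,
        seed=seed,
    )


def low_functioning_cohort(seed: int = 0, trials_per_speed: int = 2) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(
        subject_id="synthLF",
        speeds=(0.35, 0.45, 0.55, 0.65),
        trials_per_speed=trials_per_speed,
        body_mass=80.0,
        fugl_meyer=25,
        step_asym_base=0.09,
        step_asym_slope=-0.10,
        stance_asym_base=0.14,
        stance_asym_slope=-0.18,
        ds_asym_base=0.08,
        ds_asym_slope=-0.12,
        cot_trend=LOW_FN_TREND,
        seed=seed,
    )


def make_reference_trends(
    seed: int = 0,
    n_points: int = 40,
    trend: tuple[float, float] = (-3.0, 6.3),
    noise_sd: float = 0.30,
) -> pd.DataFrame:
    """Synthetic reference CoT points over speed and asymmetry covariates.

    Speeds span 0.2-0.95 m/s; CoT follows the linear trend + Gaussian noise;
    asymmetries shrink with speed (same structural rules as the synthetic
    cohorts) with their own scatter, reproducing the field's qualitative
    correlations (CoT up with asymmetry, down with speed).
    """
    rng = np.random.default_rng(seed)
    speed = rng.uniform(0.2, 0.95, n_points)
    slope, intercept = trend
    cot = intercept + slope * speed + rng.normal(0.0, noise_sd, n_points)
    d = speed - 0.6
    return pd.DataFrame(
        {
            "speed": speed,
            "cot": cot,
            "step_length_asym": np.abs(
                0.07 - 0.09 * d + rng.normal(0, 0.012, n_points)
            ),
            "stance_time_asym": np.abs(
                0.11 - 0.16 * d + rng.normal(0, 0.02, n_points)
            ),
            "double_support_asym": np.abs(
                0.065 - 0.11 * d + rng.normal(0, 0.015, n_points)
            ),
        }
    )


def make_reference_fm(seed: int = 0, n_subjects: int = 15) -> pd.DataFrame:
    """Synthetic reference mean-CoT per subject versus Fugl-Meyer score."""
    rng = np.random.default_rng(seed)
    fm = rng.integers(17, 36, n_subjects)
    cot = 8.6 - 0.13 * fm + rng.normal(0.0, 0.5, n_subjects)
    return pd.DataFrame({"fugl_meyer": fm, "cot": cot})


def build_subject(
    cohort: SyntheticCohortSpec,
    leg: SyntheticLegSpec | None = None,
    generic_seed: int = 11,
) -> tuple[SubjectData, list[GroundTruth]]:
    """Generate one synthetic subject's trials and uncalibrated model.

    Calibration uses the first trial at every speed (the remaining trials
    are evaluation data).
    """
    leg = leg if leg is not None else default_leg_spec()
    pairs = generate_cohort(cohort, leg)
    trials = [t for t, _ in pairs]
    truths = [g for _, g in pairs]
    cal_trials = [
        t for t in trials if t.meta.get("trial_index", 0) == 0
    ]
    generic = generic_model_from(leg.truth_model(), seed=generic_seed)
    subj = SubjectData(
        subject_id=cohort.subject_id,
        trials=trials,
        generic_model=generic,
        fugl_meyer=cohort.fugl_meyer,
        body_mass=cohort.body_mass,
        calibration_trials=cal_trials,
    )
    return subj, truths


def default_experiment(
    seed: int = 0, trials_per_speed: int = 2
) -> tuple[ExperimentConfig, dict[str, list[GroundTruth]]]:
    """The full two-subject 3 x 3 experiment under the default conditions."""
    leg = default_leg_spec()
    hf, hf_truth = build_subject(
        high_functioning_cohort(seed=seed, trials_per_speed=trials_per_speed),
        leg,
        generic_seed=seed + 11,
    )
    lf, lf_truth = build_subject(
        low_functioning_cohort(seed=seed + 1, trials_per_speed=trials_per_speed),
        leg,
        generic_seed=seed + 12,
    )
    config = ExperimentConfig(
        subjects=[hf, lf],
        reference_trends=make_reference_trends(seed=seed + 2),
        reference_fm=make_reference_fm(seed=seed + 3),
        seed=seed,
    )
    return config, {hf.subject_id: hf_truth, lf.subject_id: lf_truth}
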