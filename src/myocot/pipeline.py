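"""Orchestration of the 3 x 3 experiment: personalization x energetics model.

Three activation-estimation approaches —

* ``SOGen``: generic (uncalibrated) model, activations from per-frame
  static optimization;
* ``SOCal``: calibrated EMG-driven model, activations from static
  optimization;
* ``EMGCal``: calibrated EMG-driven model, activations computed directly
  from the EMG envelopes —

are crossed with three metabolic energetics models (B04, U03, U10) to
produce a cost of transport for every trial, together with gait asymmetry
outcomes, ANCOVA trend comparisons against reference experimental points,
and activation/moment RMSE diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emg_driven_calibration import (
    CalibrationProblem,
    CalibrationResult,
    activation_rmse,
    calibrate,
    predicted_moments,
)
from .gait_outcomes import trial_asymmetries
from .metabolic_models import (
    MODEL_IDS,
    cost_of_transport,
    load_constants,
    muscle_rates,
    whole_body_rate,
)
from .model import LegModel, muscle_states_from_activations
from .motion_io import GaitTrial
from .mtu_mechanics import ActivationParams, MuscleTendonParams, activation_from_envelope
from .static_optimization import _cycle_gradient, solve_trial
from .trend_statistics import COVARIATES, TrendDataset, ancova_compare, crop_reference, fm_subset

__all__ = [
    "APPROACHES",
    "SubjectData",
    "ExperimentConfig",
    "ResultBundle",
    "generic_model_from",
    "run_experiment",
    "report",
]

APPROACHES = ("SOGen", "SOCal", "EMGCal")


@dataclass
class SubjectData:
    """One subject's trials plus the uncalibrated starting model."""

    subject_id: str
    trials: list[GaitTrial]
    generic_model: LegModel
    fugl_meyer: int
    body_mass: float
    calibration_trials: list[GaitTrial] | None = None  # default: all trials


@dataclass
class ExperimentConfig:
    subjects: list[SubjectData]
    approaches: tuple[str, ...] = APPROACHES
    models: tuple[str, ...] = MODEL_IDS
    reference_trends: pd.DataFrame | None = None  # speed/asym covariates + cot
    reference_fm: pd.DataFrame | None = None  # fugl_meyer + cot per subject
    calibration_max_iter: int = 30
    include_basal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("at least one subject required")
        bad = set(self.approaches) - set(APPROACHES)
        if bad or not self.approaches:
            raise ValueError(f"approaches must be a nonempty subset of {APPROACHES}")
        bad = set(self.models) - set(MODEL_IDS)
        if bad or not self.models:
            raise ValueError(f"models must be a nonempty subset of {MODEL_IDS}")


@dataclass
class ResultBundle:
    per_trial: pd.DataFrame  # subject, trial, speed, asyms, approach, model, cot
    ancova: pd.DataFrame | None  # covariate x (approach, model): p/intercept stats
    cot_summary: pd.DataFrame  # per subject x approach x model: mean/SD CoT
    activation_rmse: pd.DataFrame  # SO approaches vs EMG-driven activations
    moment_rmse: pd.DataFrame  # per subject x approach: joint-moment RMSE
    fm_comparison: pd.DataFrame | None
    calibration: dict[str, CalibrationResult]
    config_seed: int


def generic_model_from(truth_like: LegModel, seed: int = 0, spread: float = 0.08) -> LegModel:
    """An uncalibrated "scaled generic" model derived from a model template.

    Hill parameters are perturbed by up to ``spread`` (uniform multipliers on
    l_opt and l_ts) and the EMG-to-activation parameters are reset to
    generic defaults — emulating a scaled generic model whose muscle
    force-generating properties have not been personalized.
    """
    rng = np.random.default_rng(seed)
    model = truth_like.copy()
    for name in model.muscle_names:
        m = model.muscles[name]
        f_lopt = 1.0 + spread * (2 * rng.random() - 1)
        f_lts = 1.0 + 0.25 * spread * (2 * rng.random() - 1)
        model.muscles[name] = MuscleTendonParams(
            name=m.name,
            f_max_iso=m.f_max_iso,
            l_opt=m.l_opt * f_lopt,
            l_ts=m.l_ts * f_lts,
            alpha0=m.alpha0,
            v_max=m.v_max,
            fast_twitch_fraction=m.fast_twitch_fraction,
        )
        model.activation[name] = ActivationParams(
            emd=0.04, tau_act=0.015, shape_A=0.0, emg_scale=1.0
        )
    return model


def _emg_driven_activations(model: LegModel, trial: GaitTrial) -> dict[str, np.ndarray]:
    dt = trial.angles.time[1] - trial.angles.time[0]
    return {
        name: activation_from_envelope(
            trial.emg.column(model.emg_map[name]), model.activation[name], dt
        )
        for name in model.muscle_names
    }


def _so_activations(
    model: LegModel, trial: GaitTrial
) -> tuple[dict[str, np.ndarray], float]:
    """Static-optimization activations + moment-matching RMSE (reserve use)."""
    table, diag = solve_trial(trial, model)
    rms = np.sqrt(
        np.mean([v**2 for v in diag["reserve_rms_per_dof"].values()])
    )
    return {name: table.column(name) for name in model.muscle_names}, float(rms)


def _trial_cot(
    model: LegModel,
    trial: GaitTrial,
    activations: dict[str, np.ndarray],
    excitations: dict[str, np.ndarray],
    model_ids: tuple[str, ...],
    include_basal: bool,
) -> dict[str, float]:
    dofs = model.dof_names
    q = np.column_stack([trial.angles.column(d) for d in dofs])
    qdot = _cycle_gradient(q, trial.angles.time)
    states = {
        name: muscle_states_from_activations(
            model, name, activations[name], excitations[name], q, qdot, dofs
        )
        for name in model.muscle_names
    }
    out = {}
    for mid in model_ids:
        consts = load_constants(mid)
        series = [
            muscle_rates(states[n], model.muscles[n], consts) for n in model.muscle_names
        ]
        rate = whole_body_rate(series, trial.body_mass, consts, include_basal=include_basal)
        out[mid] = cost_of_transport(rate, trial.body_mass, trial.speed, trial.t_f)
    return out


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Execute preprocess -> calibrate -> activations -> energetics -> stats."""
    rows = []
    act_rmse_rows = []
    mom_rmse_rows = []
    calibrations: dict[str, CalibrationResult] = {}

    need_cal = bool({"SOCal", "EMGCal"} & set(config.approaches))
    for subj in config.subjects:
        models: dict[str, LegModel] = {"SOGen": subj.generic_model}
        if need_cal:
            cal_trials = subj.calibration_trials or subj.trials
            problem = CalibrationProblem(trials=cal_trials, model=subj.generic_model)
            cal = calibrate(problem, max_iter=config.calibration_max_iter)
            calibrations[subj.subject_id] = cal
            models["SOCal"] = cal.model
            models["EMGCal"] = cal.model

        for t_idx, trial in enumerate(subj.trials):
            rec = trial_asymmetries(trial, trial_id=f"{subj.subject_id}_t{t_idx:02d}")
            emgcal_model = models.get("EMGCal", models["SOGen"])
            a_emg_ref = _emg_driven_activations(emgcal_model, trial)

            for approach in config.approaches:
                model = models[approach]
                if approach == "EMGCal":
                    acts = _emg_driven_activations(model, trial)
                    pred = predicted_moments(model, trial)
                    errs = np.concatenate(
                        [
                            pred.column(d) - trial.moments.column(d)
                            for d in model.dof_names
                        ]
                    )
                    mom_rms = float(np.sqrt(np.mean(errs**2)))
                else:
                    acts, mom_rms = _so_activations(model, trial)
                    per, mean_r, sd_r = activation_rmse(a_emg_ref, acts)
                    act_rmse_rows.append(
                        {
                            "subject": subj.subject_id,
                            "trial": t_idx,
                            "approach": approach,
                            "rmse_mean": mean_r,
                            "rmse_sd": sd_r,
                        }
                    )
                mom_rmse_rows.append(
                    {
                        "subject": subj.subject_id,
                        "trial": t_idx,
                        "approach": approach,
                        "moment_rmse": mom_rms,
                    }
                )
                cots = _trial_cot(
                    model, trial, acts, acts, config.models, config.include_basal
                )
                for mid, cot in cots.items():
                    rows.append(
                        {
                            "subject": subj.subject_id,
                            "trial": t_idx,
                            "speed": trial.speed,
                            "step_length_asym": rec.step_length_asym,
                            "stance_time_asym": rec.stance_time_asym,
                            "double_support_asym": rec.double_support_asym,
                            "fugl_meyer": trial.fugl_meyer,
                            "approach": approach,
                            "model": mid,
                            "cot": cot,
                        }
                    )
    per_trial = pd.DataFrame(rows)
    expected = len(config.approaches) * len(config.models)
    got = per_trial.groupby(["subject", "trial"])[["approach", "model"]].apply(
        lambda g: len(g.drop_duplicates())
    )
    if not np.all(got == expected):
        raise RuntimeError("incomplete approach x model grid in results")

    cot_summary = (
        per_trial.groupby(["subject", "approach", "model"])["cot"]
        .agg(["mean", "std"])
        .reset_index()
    )

    ancova_df = None
    if config.reference_trends is not None:
        ancova_rows = []
        for cov in COVARIATES:
            ref_cov = "speed" if cov == "speed" else cov
            if ref_cov not in config.reference_trends.columns:
                continue
            ref = crop_reference(
                config.reference_trends, per_trial["speed"].values
            )
            for approach in config.approaches:
                for mid in config.models:
                    sub = per_trial[
                        (per_trial["approach"] == approach) & (per_trial["model"] == mid)
                    ]
                    pred_ds = TrendDataset(
                        sub[cov].values, sub["cot"].values, "model_prediction", cov
                    )
                    ref_ds = TrendDataset(
                        ref[ref_cov].values, ref["cot"].values, "reference_experimental", cov
                    )
                    res = ancova_compare(pred_ds, ref_ds)
                    ancova_rows.append(
                        {
                            "covariate": cov,
                            "approach": approach,
                            "model": mid,
                            "slope_pred": res.slope_a,
                            "slope_ref": res.slope_b,
                            "p_slope": res.p_slope,
                            "p_intercept": res.p_intercept,
                            "abs_intercept_diff": res.abs_intercept_difference,
                        }
                    )
        ancova_df = pd.DataFrame(ancova_rows)

    fm_df = None
    if config.reference_fm is not None:
        fm_rows = []
        for subj in config.subjects:
            _, ref_mean, ref_sd = fm_subset(config.reference_fm, subj.fugl_meyer)
            sub = cot_summary[cot_summary["subject"] == subj.subject_id]
            for _, r in sub.iterrows():
                fm_rows.append(
                    {
                        "subject": subj.subject_id,
                        "fugl_meyer": subj.fugl_meyer,
                        "approach": r["approach"],
                        "model": r["model"],
                        "cot_mean": r["mean"],
                        "cot_sd": r["std"],
                        "ref_cot_mean": ref_mean,
                        "ref_cot_sd": ref_sd,
                        "within_2sd": bool(abs(r["mean"] - ref_mean) <= 2 * ref_sd)
                        if np.isfinite(ref_sd)
                        else False,
                    }
                )
        fm_df = pd.DataFrame(fm_rows)

    return ResultBundle(
        per_trial=per_trial,
        ancova=ancova_df,
        cot_summary=cot_summary,
        activation_rmse=pd.DataFrame(act_rmse_rows),
        moment_rmse=pd.DataFrame(mom_rmse_rows),
        fm_comparison=fm_df,
        calibration=calibrations,
        config_seed=config.seed,
    )


def report(bundle: ResultBundle, out_dir, make_figures: bool = True) -> list[Path]:
    """Write the result surfaces as CSVs (+ scatter figures); deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame | None, name: str) -> None:
        if df is None or len(df) == 0:
            return
        p = out / name
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    _write(bundle.per_trial, "per_trial.csv")
    _write(bundle.cot_summary, "cot_summary.csv")
    _write(bundle.activation_rmse, "activation_rmse.csv")
    _write(bundle.moment_rmse, "moment_rmse.csv")
    _write(bundle.fm_comparison, "fm_comparison.csv")
    if bundle.ancova is not None and len(bundle.ancova):
        _write(
            bundle.ancova.pivot_table(
                index="covariate", columns=["model", "approach"], values="p_slope"
            ).reset_index(),
            "ancova_p_slope.csv",
        )
        _write(
            bundle.ancova.pivot_table(
                index="covariate",
                columns=["model", "approach"],
                values="abs_intercept_diff",
            ).reset_index(),
            "ancova_intercept_diff.csv",
        )
        _write(bundle.ancova, "ancova_full.csv")

    if make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for cov in [c for c in COVARIATES if c in bundle.per_trial.columns]:
            fig, axes = plt.subplots(
                len(bundle.per_trial["model"].unique()),
                len(bundle.per_trial["approach"].unique()),
                figsize=(10, 8),
                squeeze=False,
                sharex=True,
                sharey=True,
            )
            for i, mid in enumerate(sorted(bundle.per_trial["model"].unique())):
                for j, app in enumerate(sorted(bundle.per_trial["approach"].unique())):
                    ax = axes[i][j]
                    sub = bundle.per_trial[
                        (bundle.per_trial["model"] == mid)
                        & (bundle.per_trial["approach"] == app)
                    ]
                    ax.scatter(sub[cov], sub["cot"], s=12, c="tab:red")
                    if i == 0:
                        ax.set_title(app, fontsize=9)
                    if j == 0:
                        ax.set_ylabel(f"{mid}\nCoT (J/kg/m)", fontsize=8)
            fig.supxlabel(cov)
            p = out / f"cot_vs_{cov}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
    return written
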