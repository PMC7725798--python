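"""Kinematic/kinetic filtering and EMG envelope extraction.

Marker-motion, GRF and moment series are low-pass filtered with a
fourth-order zero-phase Butterworth filter whose cut-off scales with the
gait-cycle period: 7 / t_f Hz for motion data (about 6 Hz at a normal
cycle period) and 3.5 / t_f Hz for the EMG envelope stage.  EMG is
high-pass filtered at 40 Hz, demeaned, rectified, then low-pass filtered
at 3.5 / t_f Hz, and each muscle's envelope is normalized to its maximum
over all of a subject's trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "FilterSpec",
    "EmgPipelineConfig",
    "variable_cutoff",
    "butter_zero_phase",
    "process_emg",
    "normalize_emg",
]


@dataclass(frozen=True)
class FilterSpec:
    """One zero-phase Butterworth pass.

    ``order`` is the order of the single-pass design.  ``convention``
    selects how "fourth-order zero-phase" is realized: ``"design"`` (the
    default) applies an order-4 design forward-backward (effective 8th-order
    magnitude); ``"effective"`` applies an order-2 design forward-backward so
    the combined magnitude response is 4th order.
    """

    cutoff_hz: float
    kind: Literal["lowpass", "highpass"] = "lowpass"
    order: int = 4
    convention: Literal["design", "effective"] = "design"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be even and positive")


@dataclass(frozen=True)
class EmgPipelineConfig:
    highpass_hz: float = 40.0
    lowpass_numerator: float = 3.5  # Hz·s, divided by t_f
    motion_lowpass_numerator: float = 7.0

    def __post_init__(self) -> None:
        if min(self.highpass_hz, self.lowpass_numerator, self.motion_lowpass_numerator) <= 0:
            raise ValueError("all pipeline constants must be positive")


def variable_cutoff(numerator: float, t_f: float) -> float:
    """Cycle-period-scaled cut-off frequency, numerator / t_f Hz."""
    if t_f <= 0:
        raise ValueError("t_f must be positive")
    return numerator / t_f


def butter_zero_phase(signal: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Forward-backward Butterworth filtering (zero phase lag).

    Edge effects are reduced by odd-reflection padding sized to the
    filter's impulse-response length (ten cutoff periods, but at least 3x
    the filter order and at most the signal length), which keeps the
    forward-backward pass reversal-symmetric to ~1e-12.  DC gain is
    exactly 1 for lowpass; a symmetric input stays symmetric.
    """
    x = np.asarray(signal, dtype=float)
    nyq = fs / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz")
    order = spec.order if spec.convention == "design" else spec.order // 2
    if x.shape[-1] < 3 * spec.order:
        raise ValueError("signal too short for stable zero-phase filtering")
    sos = butter(order, spec.cutoff_hz / nyq, btype=spec.kind, output="sos")
    padlen = min(
        x.shape[-1] - 1,
        max(3 * spec.order, int(round(10.0 * fs / spec.cutoff_hz))),
    )
    return sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def process_emg(
    raw: np.ndarray,
    fs: float,
    t_f: float,
    cfg: EmgPipelineConfig = EmgPipelineConfig(),
) -> np.ndarray:
    """Raw EMG -> linear envelope.

    In order: 40 Hz zero-phase high-pass, demean, full-wave rectify,
    zero-phase low-pass at 3.5/t_f Hz, then clip at 0 (low-pass ringing can
    dip an envelope slightly negative, which is nonphysical).
    """
    if fs <= 2 * cfg.highpass_hz:
        raise ValueError("sampling rate too low for the 40 Hz high-pass stage")
    x = butter_zero_phase(raw, fs, FilterSpec(cfg.highpass_hz, "highpass"))
    x = x - np.mean(x)
    x = np.abs(x)
    lp = variable_cutoff(cfg.lowpass_numerator, t_f)
    x = butter_zero_phase(x, fs, FilterSpec(lp, "lowpass"))
    return np.clip(x, 0.0, None)


def normalize_emg(
    envelopes: dict[str, list[np.ndarray]],
) -> tuple[dict[str, list[np.ndarray]], dict[str, float]]:
    """Divide each muscle's envelopes by its maximum over all trials.

    Returns the normalized collection and the per-muscle scale record (the
    maxima used), retained for reporting.  A muscle whose envelope is zero
    in every trial cannot be normalized and is an error.
    """
    if not envelopes:
        raise ValueError("no muscles given")
    out: dict[str, list[np.ndarray]] = {}
    scales: dict[str, float] = {}
    for muscle, trials in envelopes.items():
        if not trials:
            raise ValueError(f"muscle {muscle!r} has no trials")
        peak = max(float(np.max(tr)) for tr in trials)
        if peak <= 0:
            raise ValueError(f"muscle {muscle!r} is identically zero in all trials")
        out[muscle] = [np.asarray(tr, float) / peak for tr in trials]
        scales[muscle] = peak
    return out, scales
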