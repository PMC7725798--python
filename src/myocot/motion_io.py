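"""Motion-table I/O, gait-cycle segmentation and 101-point normalization.

Motion tables are the plain-text time-series format used throughout gait
analysis: an optional ``key=value`` header block terminated by ``endheader``,
a row of column labels (first column ``time``), then whitespace-delimited
numeric rows.  A CSV dialect with identical semantics is also supported.

All quantities are SI at load time: rad, N·m, N, m, s.  A header key
``units=deg`` converts angle columns to radians on read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "MotionTable",
    "GaitEvents",
    "GaitTrial",
    "read_motion_table",
    "write_motion_table",
    "segment_cycles",
    "resample_cycle",
]

Dialect = Literal["sto_mot", "csv"]


class MotionParseError(ValueError):
    """Raised when a motion-table file cannot be parsed."""


@dataclass
class MotionTable:
    """A labeled numeric time-series table (frames x columns)."""

    column_labels: list[str]
    time: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # (n_frames, n_columns)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.time.shape[0]:
            raise ValueError(
                f"time has {self.time.shape[0]} frames but values has "
                f"{self.values.shape[0]} rows"
            )
        if len(self.column_labels) != self.values.shape[1]:
            raise ValueError("number of labels does not match number of columns")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError("column labels must be unique")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.time)):
            raise ValueError("motion table contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.column_labels.index(label)
        except ValueError:
            raise KeyError(f"no column named {label!r}") from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_labels)
        df.insert(0, "time", self.time)
        return df

    @classmethod
    def from_arrays(cls, time, columns: dict[str, np.ndarray]) -> "MotionTable":
        labels = list(columns)
        values = np.column_stack([np.asarray(columns[k], float) for k in labels])
        return cls(labels, np.asarray(time, float), values)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) for both legs within one cycle [0, t_f)."""

    hs_paretic: float
    to_paretic: float
    hs_nonparetic: float
    to_nonparetic: float
    t_f: float

    def __post_init__(self) -> None:
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")
        for name in ("hs_paretic", "to_paretic", "hs_nonparetic", "to_nonparetic"):
            v = getattr(self, name)
            if not 0 <= v <= self.t_f:
                raise ValueError(f"{name}={v} outside [0, t_f={self.t_f}]")
        for hs, to, leg in (
            (self.hs_paretic, self.to_paretic, "paretic"),
            (self.hs_nonparetic, self.to_nonparetic, "nonparetic"),
        ):
            st = cyclic_duration(hs, to, self.t_f)
            if not 0 < st < self.t_f:
                raise ValueError(f"{leg} stance duration {st} not in (0, t_f)")


def cyclic_duration(start: float, end: float, t_f: float) -> float:
    """Duration from ``start`` to ``end`` going forward in time, modulo ``t_f``."""
    return (end - start) % t_f


@dataclass
class GaitTrial:
    """One gait cycle's synchronized data plus subject metadata.

    After processing, all tables share the 101-sample normalized time base
    (0..100% gait cycle, heel strike of the paretic leg at index 0).
    """

    subject_id: str
    side_paretic: Literal["left", "right"]
    speed: float  # m/s
    body_mass: float  # kg
    fugl_meyer: int
    t_f: float  # cycle period, s
    angles: MotionTable  # rad
    moments: MotionTable  # N·m
    grf: MotionTable  # N
    emg: MotionTable  # normalized envelopes in [0, 1]
    pelvis_pos: np.ndarray  # fore-aft, m
    foot_pos_L: np.ndarray
    foot_pos_R: np.ndarray
    events: GaitEvents
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0.1 <= self.speed <= 2.0:
            warnings.warn(
                f"walking speed {self.speed} m/s outside plausible [0.1, 2.0]",
                stacklevel=2,
            )
        n = self.angles.n_frames
        for tbl_name in ("moments", "grf", "emg"):
            if getattr(self, tbl_name).n_frames != n:
                raise ValueError(f"{tbl_name} frame count differs from angles")
        for arr_name in ("pelvis_pos", "foot_pos_L", "foot_pos_R"):
            arr = np.asarray(getattr(self, arr_name), float)
            setattr(self, arr_name, arr)
            if arr.shape[0] != n:
                raise ValueError(f"{arr_name} length differs from angles")

    @property
    def foot_pos_paretic(self) -> np.ndarray:
        return self.foot_pos_L if self.side_paretic == "left" else self.foot_pos_R

    @property
    def foot_pos_nonparetic(self) -> np.ndarray:
        return self.foot_pos_R if self.side_paretic == "left" else self.foot_pos_L


_ANGLE_HINTS = ("angle", "flexion", "adduction", "rotation", "_rad", "_deg")


def read_motion_table(path, dialect: Dialect = "sto_mot") -> MotionTable:
    """Read a motion-table text file.

    ``sto_mot``: optional header block of ``key=value`` lines terminated by
    ``endheader``, then a tab/whitespace-delimited label row and numeric rows.
    ``csv``: comma-separated with the label row first.  The first column must
    be ``time`` and strictly increasing.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    if dialect == "sto_mot":
        # header block present iff an "endheader" sentinel exists
        sentinel = next(
            (k for k, ln in enumerate(text) if ln.strip().lower() == "endheader"), None
        )
        if sentinel is not None:
            for k in range(sentinel):
                line = text[k].strip()
                if not line:
                    continue
                if "=" in line:
                    key, _, val = line.partition("=")
                    header[key.strip()] = val.strip()
                # bare lines (e.g. a file title) are tolerated
            i = sentinel + 1
        sep = None  # any whitespace
    elif dialect == "csv":
        sep = ","
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    while i < len(text) and not text[i].strip():
        i += 1
    if i >= len(text):
        raise MotionParseError(f"{path}: no label row found")
    labels = [s.strip() for s in (text[i].split(sep) if sep else text[i].split())]
    if not labels or labels[0].lower() != "time":
        raise MotionParseError(f"{path}: line {i + 1}: first column must be 'time'")
    i += 1

    rows = []
    ncol = len(labels)
    for lineno in range(i, len(text)):
        line = text[lineno].strip()
        if not line:
            continue
        parts = line.split(sep) if sep else line.split()
        if len(parts) != ncol:
            raise MotionParseError(
                f"{path}: line {lineno + 1}: expected {ncol} fields, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as e:
            raise MotionParseError(f"{path}: line {lineno + 1}: {e}") from None
    if not rows:
        raise MotionParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    time, values = data[:, 0], data[:, 1:]
    if time.size >= 2 and not np.all(np.diff(time) > 0):
        raise MotionParseError(f"{path}: time column is not strictly increasing")

    if header.get("units", "").lower() in ("deg", "degrees"):
        for j, lab in enumerate(labels[1:]):
            if any(h in lab.lower() for h in _ANGLE_HINTS):
                values[:, j] = np.deg2rad(values[:, j])
    return MotionTable(labels[1:], time, values)


def write_motion_table(table: MotionTable, path, dialect: Dialect = "sto_mot") -> None:
    """Write a motion table; round-trips with :func:`read_motion_table`."""
    if table.n_frames == 0:
        raise ValueError("refusing to write an empty (0-frame) table")
    path = Path(path)
    labels = ["time"] + list(table.column_labels)
    data = np.column_stack([table.time, table.values])
    with path.open("w") as fh:
        if dialect == "sto_mot":
            fh.write(f"nRows={data.shape[0]}\nnColumns={data.shape[1]}\nendheader\n")
            fh.write("\t".join(labels) + "\n")
            for row in data:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
        elif dialect == "csv":
            fh.write(",".join(labels) + "\n")
            for row in data:
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def _sustained_crossings(
    t: np.ndarray, y: np.ndarray, threshold: float, min_dwell_s: float
) -> tuple[list[float], list[float]]:
    """Upward/downward threshold crossings sustained for at least min_dwell_s.

    Crossing times are linearly interpolated between samples.  A crossing
    counts only if the signal stays on the new side of the threshold for the
    dwell time (debounce against sensor noise near the threshold).
    """
    above = y >= threshold
    ups, downs = [], []
    for k in range(1, len(y)):
        if above[k] == above[k - 1]:
            continue
        # interpolated crossing time
        frac = (threshold - y[k - 1]) / (y[k] - y[k - 1])
        tc = t[k - 1] + frac * (t[k] - t[k - 1])
        # debounce: state must persist until tc + dwell (or the record ends)
        t_end = tc + min_dwell_s
        m = k
        ok = True
        while m < len(y) and t[m] < t_end:
            if above[m] != above[k]:
                ok = False
                break
            m += 1
        if ok:
            (ups if above[k] else downs).append(tc)
    return ups, downs


def segment_cycles(
    continuous: MotionTable,
    grf: MotionTable,
    side: Literal["left", "right"],
    threshold: float = 20.0,
    min_dwell_s: float = 0.050,
) -> list[tuple[float, float]]:
    """Heel-strike-to-heel-strike windows from the vertical GRF of one foot.

    Heel strike is an upward crossing of the vertical GRF through ``threshold``
    (N) sustained >= ``min_dwell_s``; toe-off the corresponding downward
    crossing.  Returns consecutive (start_s, end_s) windows; empty if there
    are fewer than two heel strikes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    col = _vertical_grf_label(grf, side)
    y = grf.column(col)
    ups, _ = _sustained_crossings(grf.time, y, threshold, min_dwell_s)
    return [(ups[k], ups[k + 1]) for k in range(len(ups) - 1)]


def detect_events(
    grf: MotionTable,
    side: Literal["left", "right"],
    threshold: float = 20.0,
    min_dwell_s: float = 0.050,
) -> tuple[list[float], list[float]]:
    """(heel_strikes, toe_offs) for one foot; same rule as segment_cycles."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y = grf.column(_vertical_grf_label(grf, side))
    return _sustained_crossings(grf.time, y, threshold, min_dwell_s)


def _vertical_grf_label(grf: MotionTable, side: str) -> str:
    want = side.lower()
    for lab in grf.column_labels:
        low = lab.lower()
        if want in low and ("vy" in low or "vertical" in low or low.endswith("_v")):
            return lab
    raise KeyError(f"no vertical GRF column for side {side!r} in {grf.column_labels}")


def resample_cycle(
    table: MotionTable, start_s: float, end_s: float, n: int = 101
) -> MotionTable:
    """Linearly resample ``[start_s, end_s]`` onto ``n`` uniform frames.

    The output time base is the absolute window times; frame 0 and frame n-1
    are the interpolated values at the window boundaries.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    t0, t1 = table.time[0], table.time[-1]
    if not (t0 <= start_s < end_s <= t1 + 1e-12):
        raise ValueError(
            f"window [{start_s}, {end_s}] outside table span [{t0}, {t1}]"
        )
    new_t = np.linspace(start_s, min(end_s, t1), n)
    new_vals = np.empty((n, table.values.shape[1]))
    for j in range(table.values.shape[1]):
        new_vals[:, j] = np.interp(new_t, table.time, table.values[:, j])
    return MotionTable(list(table.column_labels), new_t, new_vals)
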