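"""Readers and writers for the on-disk artifacts.

Raw accelerometer logs are CSV with header ``t_us,ax,ay,az`` (integer
microseconds since recording start; accelerations in m/s^2).  Ground-truth
maneuver intervals are CSV with header ``start_s,end_s,state``.  Bout lists
and mobility metrics are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

STATIONARY = "stationary"
MOVING = "moving"


@dataclass
class RawRecording:
    """An ordered, timestamped tri-axial accelerometer recording.

    ``t_us`` is integer microseconds since recording start and must be
    strictly increasing; ``ax``, ``ay``, ``az`` are accelerations in m/s^2
    along the device's own axes (no reorientation is applied anywhere in the
    pipeline — downstream processing is placement-invariant by design).
    """

    t_us: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    device_id: str = ""

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        for name in ("ax", "ay", "az"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_us)
        if n < 2:
            raise InsufficientDataError(
                f"a recording needs at least 2 samples, got {n}"
            )
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name!r} length != timestamp length")
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite value in column {name!r}")
        if self.t_us[0] < 0:
            raise ValidationError("timestamps must be >= 0")
        bad = np.nonzero(np.diff(self.t_us) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1} "
                f"(t_us={int(self.t_us[bad[0] + 1])})"
            )

    @property
    def n(self) -> int:
        return len(self.t_us)

    def __len__(self) -> int:
        return len(self.t_us)

    @property
    def t_s(self) -> np.ndarray:
        """Timestamps in float seconds."""
        return self.t_us * 1e-6

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            np.array_equal(self.t_us, other.t_us)
            and np.allclose(self.ax, other.ax, atol=0, rtol=0)
            and np.allclose(self.ay, other.ay, atol=0, rtol=0)
            and np.allclose(self.az, other.az, atol=0, rtol=0)
        )


@dataclass
class IntervalTruth:
    """Ordered, non-overlapping ground-truth maneuver intervals (seconds)."""

    start_s: np.ndarray
    end_s: np.ndarray
    state: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        self.state = list(self.state)
        n = len(self.start_s)
        if len(self.end_s) != n or len(self.state) != n:
            raise ValidationError("truth columns have mismatched lengths")
        for s in self.state:
            if s not in (STATIONARY, MOVING):
                raise ValidationError(f"unknown state {s!r}")
        if np.any(self.end_s <= self.start_s):
            raise ValidationError("every interval must satisfy end > start")
        if n > 1:
            if np.any(np.diff(self.start_s) < 0):
                raise ValidationError("intervals must be sorted by start")
            if np.any(self.start_s[1:] < self.end_s[:-1] - 1e-12):
                raise ValidationError("intervals must not overlap")

    def __len__(self) -> int:
        return len(self.start_s)

    def moving_intervals(self) -> np.ndarray:
        """(m, 2) array of (start, end) for the moving intervals."""
        idx = [i for i, s in enumerate(self.state) if s == MOVING]
        return np.column_stack([self.start_s[idx], self.end_s[idx]]) if idx else np.empty((0, 2))


@dataclass
class Bout:
    """One period of continuous wheelchair movement."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("bout end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MobilityMetrics:
    """Summary mobility metrics derived from a bout list."""

    n_bouts: int
    accumulated_movement: float
    max_continuous: float
    mean_continuous: float


def read_recording(path, device_id: str = "") -> RawRecording:
    """Read a raw accelerometer CSV, dropping rows with non-finite values."""
    df = pd.read_csv(path)
    required = ["t_us", "ax", "ay", "az"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header must be t_us,ax,ay,az")
    df = df[required].apply(pd.to_numeric, errors="coerce")
    df = df[np.isfinite(df).all(axis=1)]
    df = df.sort_values("t_us", kind="stable")
    return RawRecording(
        t_us=df["t_us"].to_numpy(dtype=np.int64),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        device_id=device_id,
    )


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording as CSV, accelerations at 6 decimal places."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_us,ax,ay,az\n")
        for t, x, y, z in zip(rec.t_us, rec.ax, rec.ay, rec.az):
            fh.write(f"{int(t)},{x:.6f},{y:.6f},{z:.6f}\n")


def read_truth(path) -> IntervalTruth:
    df = pd.read_csv(path)
    required = ["start_s", "end_s", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header must be start_s,end_s,state")
    return IntervalTruth(
        start_s=df["start_s"].to_numpy(dtype=float),
        end_s=df["end_s"].to_numpy(dtype=float),
        state=[str(s).strip() for s in df["state"]],
    )


def write_truth(truth: IntervalTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("start_s,end_s,state\n")
        for s, e, st in zip(truth.start_s, truth.end_s, truth.state):
            fh.write(f"{s:.6f},{e:.6f},{st}\n")


def write_bouts(bouts: list, path) -> None:
    payload = [
        {"start": float(b.start), "end": float(b.end), "duration": float(b.duration)}
        for b in bouts
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_bouts(path) -> list:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [Bout(start=item["start"], end=item["end"]) for item in payload]


def write_metrics(metrics: MobilityMetrics, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(metrics), fh, indent=2)
        fh.write("\n")


def read_metrics(path) -> MobilityMetrics:
    with open(path, encoding="utf-8") as fh:
        return MobilityMetrics(**json.load(fh))
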