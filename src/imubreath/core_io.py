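"""Domain types and file I/O for abdominal-IMU breathing analysis.

A recording is a uniformly sampled multichannel time series: three Euler
angles (degrees) and three linear accelerations (m/s²) from a single
abdomen-mounted IMU, nominally sampled at 330 Hz.  Mid-recording dropouts
are represented as masked samples (``valid_mask``), never as deleted rows,
so absolute time is preserved.  Annotations are sparse labeled intervals
(breathing vs. noise); any span not covered by an interval is unlabeled.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger("imubreath")

#: Closed label vocabulary.  Everything not covered by an interval is UNLABELED.
LABEL_BREATHING = "breathing"
LABEL_NOISE = "noise"

#: Integer label codes used throughout the pipeline (breathing is the positive class).
CODE_BREATHING = 1
CODE_NOISE = 0
CODE_UNLABELED = -1

RECORDING_COLUMNS = ("t_s", "euler_x", "euler_y", "euler_z", "acc_x", "acc_y", "acc_z", "gap")
ANNOTATION_COLUMNS = ("start_s", "end_s", "label")

NOMINAL_RATE_HZ = 330.0


@dataclass
class ImuRecording:
    """One subject's IMU time series on a uniform sample grid.

    Parameters
    ----------
    subject_id
        Opaque identifier; used for grouped cross-validation.
    sampling_rate_hz
        Samples per second (nominal 330).  Time of sample ``i`` is
        ``i / sampling_rate_hz``.
    euler
        ``(n_samples, 3)`` Euler angles x, y, z in degrees.
    acc
        ``(n_samples, 3)`` linear accelerations x, y, z in m/s².
    valid_mask
        ``(n_samples,)`` boolean; ``False`` inside signal gaps.
    """

    subject_id: str
    sampling_rate_hz: float
    euler: np.ndarray
    acc: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.euler = np.asarray(self.euler, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.euler.ndim != 2 or self.euler.shape[1] != 3:
            raise DataError(f"euler must be (n, 3); got {self.euler.shape}")
        if self.acc.shape != self.euler.shape:
            raise DataError(
                f"acc shape {self.acc.shape} does not match euler shape {self.euler.shape}"
            )
        if self.valid_mask.shape != (self.euler.shape[0],):
            raise DataError("valid_mask length does not match channel length")
        if not self.sampling_rate_hz > 0:
            raise DataError(f"sampling_rate_hz must be positive; got {self.sampling_rate_hz}")

    @property
    def n_samples(self) -> int:
        return self.euler.shape[0]

    @property
    def n_valid(self) -> int:
        """Number of non-gap samples (the symbol N in window bookkeeping)."""
        return int(self.valid_mask.sum())

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def raw_channels(self) -> np.ndarray:
        """The six raw channels stacked as ``(n_samples, 6)``: euler then acc."""
        return np.hstack([self.euler, self.acc])


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise DataError(f"interval start {self.start_s} must precede end {self.end_s}")
        if self.label not in (LABEL_BREATHING, LABEL_NOISE):
            raise DataError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping labeled intervals; uncovered time is unlabeled."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start_s < a.end_s:
                raise DataError(
                    f"overlapping intervals: [{a.start_s}, {a.end_s}] and [{b.start_s}, {b.end_s}]"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def sample_labels(self, n_samples: int, sampling_rate_hz: float) -> np.ndarray:
        """Per-sample integer codes (1 breathing, 0 noise, −1 unlabeled).

        A sample at time ``i / rate`` belongs to the half-open interval
        ``[start_s, end_s)`` that contains it.
        """
        codes = np.full(n_samples, CODE_UNLABELED, dtype=np.int8)
        t = np.arange(n_samples) / sampling_rate_hz
        for iv in self.intervals:
            code = CODE_BREATHING if iv.label == LABEL_BREATHING else CODE_NOISE
            codes[(t >= iv.start_s) & (t < iv.end_s)] = code
        return codes

    def total_labeled_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)


@dataclass
class PipelineConfig:
    """Resolved knobs of the classification + segmentation pipeline.

    Defaults follow the best-performing published configuration: 2000-sample
    windows (≈6.06 s at 330 Hz) advanced by 100 samples, probability
    threshold 0.5, a 5-window decision smoother, suppression of activations
    shorter than 3 windows, and a 0.5 s orientation-norm smoother.
    """

    window_size: int = 2000
    step: int = 100
    threshold: float = 0.5
    smoothing_len: int = 5
    min_run: int = 3
    norm_smooth_s: float = 0.5
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ConfigError("window_size must be positive")
        if self.step <= 0:
            raise ConfigError("step must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must be in (0, 1)")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        if self.smoothing_len < 1:
            raise ConfigError("smoothing_len must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")

    def window_seconds(self, sampling_rate_hz: float = NOMINAL_RATE_HZ) -> float:
        return self.window_size / sampling_rate_hz

    def step_seconds(self, sampling_rate_hz: float = NOMINAL_RATE_HZ) -> float:
        return self.step / sampling_rate_hz

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_resolved(self, seed: int | None = None) -> None:
        logger.info("resolved config: %s (seed=%s)", self.to_dict(), self.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Readers / writers


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    sampling_rate_hz: float | None = None,
) -> ImuRecording:
    """Read a recording CSV (columns t_s, euler_*, acc_*, gap).

    Timestamps are required to be strictly increasing.  If they deviate from
    a uniform grid by more than half a sample period, channels are linearly
    resampled onto the nominal grid implied by the mean rate (all window ↔
    seconds arithmetic assumes uniform spacing).
    """
    path = Path(path)
    # round_trip parsing: shortest-repr floats must survive the CSV bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise DataError(f"{path.name}: timestamps are not strictly increasing")

    if sampling_rate_hz is None:
        if len(t) >= 2:
            sampling_rate_hz = (len(t) - 1) / (t[-1] - t[0])
        else:
            sampling_rate_hz = NOMINAL_RATE_HZ

    euler = df[["euler_x", "euler_y", "euler_z"]].to_numpy(dtype=float)
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    gap = df["gap"].to_numpy(dtype=float) != 0

    grid = t[0] + np.arange(len(t)) / sampling_rate_hz if len(t) else t
    if len(t) >= 2 and np.max(np.abs(t - grid)) > 0.5 / sampling_rate_hz:
        euler = np.column_stack([np.interp(grid, t, euler[:, j]) for j in range(3)])
        acc = np.column_stack([np.interp(grid, t, acc[:, j]) for j in range(3)])
        gap = np.interp(grid, t, gap.astype(float)) > 0.5

    return ImuRecording(
        subject_id=subject_id or path.stem,
        sampling_rate_hz=float(sampling_rate_hz),
        euler=euler,
        acc=acc,
        valid_mask=~gap,
    )


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording CSV that round-trips sample values bit-exactly."""
    df = pd.DataFrame(
        {
            "t_s": rec.time_s,
            "euler_x": rec.euler[:, 0],
            "euler_y": rec.euler[:, 1],
            "euler_z": rec.euler[:, 2],
            "acc_x": rec.acc[:, 0],
            "acc_y": rec.acc[:, 1],
            "acc_z": rec.acc[:, 2],
            "gap": (~rec.valid_mask).astype(int),
        }
    )
    # repr-precision floats survive a CSV round trip exactly
    df.to_csv(path, index=False, float_format=None)


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an interval CSV (start_s, end_s, label ∈ {breathing, noise})."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and df.columns.size == 0:
        return AnnotationTrack([])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    intervals = [
        Interval(float(r.start_s), float(r.end_s), str(r.label).strip().lower())
        for r in df.itertuples()
    ]
    return AnnotationTrack(intervals)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.label) for iv in track.intervals],
        columns=list(ANNOTATION_COLUMNS),
    ).to_csv(path, index=False)


def contiguous_valid_runs(valid_mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Half-open ``[start, stop)`` index ranges of maximal valid runs."""
    mask = np.asarray(valid_mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
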