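"""Per-time-step feature engineering and train-only z-score normalization.

Six raw channels (Euler x/y/z in degrees, linear acceleration x/y/z in m/s²)
are expanded to 14: the raw channels, their first-order differences, and the
Euclidean norms of the Euler and acceleration 3-vectors.  The channel order
is frozen (see :data:`FEATURE_NAMES`); models and serialized normalization
statistics rely on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import ImuRecording
from .errors import DegenerateDataError

#: Frozen 14-channel order.  Δ channels are plain sample-to-sample differences
#: (not scaled by the sampling interval); norms are Euclidean.
FEATURE_NAMES: tuple[str, ...] = (
    "euler_x",
    "euler_y",
    "euler_z",
    "acc_x",
    "acc_y",
    "acc_z",
    "d_euler_x",
    "d_euler_y",
    "d_euler_z",
    "d_acc_x",
    "d_acc_y",
    "d_acc_z",
    "euler_norm",
    "acc_norm",
)
N_FEATURES = len(FEATURE_NAMES)


@dataclass
class FeatureSeries:
    """(n_samples, 14) feature matrix with the recording's validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    sampling_rate_hz: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) features; got {self.values.shape}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class NormStats:
    """Per-channel mean/sd fitted on training data only (population convention)."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.sd = np.asarray(self.sd, dtype=float).reshape(-1)
        if self.mean.shape != (N_FEATURES,) or self.sd.shape != (N_FEATURES,):
            raise ValueError(f"stats must have {N_FEATURES} channels")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": list(FEATURE_NAMES),
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                    "fitted_on": self.fitted_on,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        raw = json.loads(Path(path).read_text())
        if tuple(raw["feature_names"]) != FEATURE_NAMES:
            raise ValueError("serialized stats use a different feature order")
        return cls(np.array(raw["mean"]), np.array(raw["sd"]), raw.get("fitted_on", ""))


def engineer_features(rec: ImuRecording) -> FeatureSeries:
    """Expand the six raw channels to the 14-channel feature series.

    Differences are computed on the raw (unnormalized) signals with a zero
    prepended so length is preserved; a difference whose left neighbour falls
    in a gap is also zeroed, so no feature mixes valid and masked samples.
    """
    if rec.n_samples < 2:
        raise DegenerateDataError("need at least 2 samples to compute differences")
    raw = rec.raw_channels()  # (n, 6)
    diff = np.vstack([np.zeros((1, 6)), np.diff(raw, axis=0)])
    boundary = np.flatnonzero(~rec.valid_mask[:-1]) + 1  # first sample after each gap
    diff[boundary] = 0.0
    euler_norm = np.linalg.norm(rec.euler, axis=1, keepdims=True)
    acc_norm = np.linalg.norm(rec.acc, axis=1, keepdims=True)
    values = np.hstack([raw, diff, euler_norm, acc_norm])
    return FeatureSeries(values, rec.valid_mask.copy(), rec.sampling_rate_hz, rec.subject_id)


def _stack_samples(data: "np.ndarray | FeatureSeries | Iterable") -> np.ndarray:
    if isinstance(data, FeatureSeries):
        return data.values[data.valid_mask]
    if isinstance(data, np.ndarray):
        return data.reshape(-1, data.shape[-1])
    parts = [_stack_samples(part) for part in data]
    if not parts:
        raise DegenerateDataError("empty training collection")
    return np.vstack(parts)


def fit_norm_stats(
    training: "np.ndarray | FeatureSeries | Sequence", fitted_on: str = ""
) -> NormStats:
    """Fit per-channel mean and population (1/n) standard deviation.

    ``training`` may be a FeatureSeries (valid samples only), an array whose
    last axis is the channel axis — e.g. stacked training windows
    ``(n_windows, w, 14)`` — or a sequence of either.
    """
    samples = _stack_samples(training)
    if samples.size == 0:
        raise DegenerateDataError("empty training collection")
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0)  # ddof=0
    dead = np.flatnonzero(sd <= 0)
    if dead.size:
        names = [FEATURE_NAMES[i] for i in dead]
        raise DegenerateDataError(f"zero-variance channel(s): {names}")
    return NormStats(mean, sd, fitted_on)


def apply_norm(data, stats: NormStats):
    """Z-score ``(x − mean) / sd`` per channel.

    Accepts a FeatureSeries (returns a new FeatureSeries) or any array whose
    last axis has 14 channels (returns an array of the same shape).
    """
    if isinstance(data, FeatureSeries):
        return FeatureSeries(
            (data.values - stats.mean) / stats.sd,
            data.valid_mask,
            data.sampling_rate_hz,
            data.subject_id,
        )
    arr = np.asarray(data, dtype=float)
    return (arr - stats.mean) / stats.sd


def invert_norm(data, stats: NormStats):
    """Inverse of :func:`apply_norm` (mainly for testing round-trips)."""
    if isinstance(data, FeatureSeries):
        return FeatureSeries(
            data.values * stats.sd + stats.mean,
            data.valid_mask,
            data.sampling_rate_hz,
            data.subject_id,
        )
    return np.asarray(data, dtype=float) * stats.sd + stats.mean
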