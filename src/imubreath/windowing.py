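"""Sliding-window extraction, window labeling, and class-imbalance weights.

Windows are half-open sample ranges ``[start, start + w)`` advanced by a
fixed stride within each maximal gap-free run of the recording; a window
never straddles a gap.  Each window is labeled from the annotated intervals
by a purity rule, and balanced class weights ``n_total / (n_classes · n_i)``
compensate the breathing/noise imbalance during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .core_io import (
    CODE_BREATHING,
    CODE_NOISE,
    CODE_UNLABELED,
    AnnotationTrack,
    PipelineConfig,
    contiguous_valid_runs,
)
from .errors import DegenerateDataError
from .features import N_FEATURES, FeatureSeries

#: Minimum fraction of a window's samples that must carry a label for the
#: window to inherit it.  Windows mixing breathing and noise samples, or
#: failing purity, stay unlabeled (excluded from training and metrics).
PURITY = 0.8


@dataclass
class WindowSet:
    """Stacked fixed-length windows with labels, subjects and start indices."""

    windows: np.ndarray  # (n_windows, window_size, 14)
    labels: np.ndarray  # int8: 1 breathing, 0 noise, −1 unlabeled
    subject_ids: np.ndarray  # str per window
    start_indices: np.ndarray  # 0-based sample index per window
    window_size: int
    step: int
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.windows)
        if not (len(self.labels) == len(self.subject_ids) == len(self.start_indices) == n):
            raise ValueError("per-window arrays disagree in length")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != CODE_UNLABELED

    @property
    def start_times_s(self) -> np.ndarray:
        return self.start_indices / self.sampling_rate_hz

    def counts(self) -> tuple[int, int]:
        """(n_breathing, n_noise) over labeled windows."""
        return int((self.labels == CODE_BREATHING).sum()), int((self.labels == CODE_NOISE).sum())

    def select(self, idx) -> "WindowSet":
        return WindowSet(
            self.windows[idx],
            self.labels[idx],
            self.subject_ids[idx],
            self.start_indices[idx],
            self.window_size,
            self.step,
            self.sampling_rate_hz,
        )

    @staticmethod
    def concatenate(parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        return WindowSet(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.start_indices for p in parts]),
            first.window_size,
            first.step,
            first.sampling_rate_hz,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("windows", data=self.windows.astype(np.float32))
            fh.create_dataset("labels", data=self.labels)
            fh.create_dataset("subject_ids", data=np.asarray(self.subject_ids, dtype="S"))
            fh.create_dataset("start_indices", data=self.start_indices)
            fh.attrs["window_size"] = self.window_size
            fh.attrs["step"] = self.step
            fh.attrs["sampling_rate_hz"] = self.sampling_rate_hz

    @classmethod
    def from_hdf5(cls, path) -> "WindowSet":
        with h5py.File(path, "r") as fh:
            return cls(
                fh["windows"][:].astype(float),
                fh["labels"][:],
                fh["subject_ids"][:].astype(str),
                fh["start_indices"][:],
                int(fh.attrs["window_size"]),
                int(fh.attrs["step"]),
                float(fh.attrs["sampling_rate_hz"]),
            )


@dataclass
class ClassWeightSummary:
    """Balanced class weights w_i = n_total / (n_classes · n_i)."""

    n_total: int
    n_breathing: int
    n_noise: int
    weight_breathing: float
    weight_noise: float
    n_classes: int = 2

    def as_sample_weights(self, labels: np.ndarray) -> np.ndarray:
        """Per-window loss weights for a 0/1 label vector."""
        return np.where(labels == CODE_BREATHING, self.weight_breathing, self.weight_noise)


def count_windows(n_valid: int, w: int, step: int) -> int:
    """Number of stride-grid windows fitting in one contiguous run.

    ``floor((n_valid − w) / step) + 1`` when at least one window fits, else 0.
    """
    if w <= 0 or step <= 0:
        raise ValueError("w and step must be positive")
    if n_valid < w:
        return 0
    return (n_valid - w) // step + 1


def window_starts(run_start: int, run_stop: int, w: int, step: int) -> np.ndarray:
    """Start indices of all windows inside the half-open run [run_start, run_stop)."""
    n = count_windows(run_stop - run_start, w, step)
    return run_start + step * np.arange(n)


def make_windows(
    fs: FeatureSeries, ann: AnnotationTrack, cfg: PipelineConfig
) -> WindowSet:
    """Slice a feature series into labeled overlapping windows.

    Windows are laid on the stride grid of each maximal valid run (the grid
    restarts after a gap, mirroring the per-run window count), so no window
    contains masked samples.  A window is labeled breathing (noise) when at
    least 80% of its samples lie in breathing (noise) intervals and none lie
    in the opposite class; everything else is kept but flagged unlabeled.
    """
    w, step = cfg.window_size, cfg.step
    codes = ann.sample_labels(fs.n_samples, fs.sampling_rate_hz)
    # prefix sums for O(1) per-window label counts
    is_b = np.concatenate([[0], np.cumsum(codes == CODE_BREATHING)])
    is_n = np.concatenate([[0], np.cumsum(codes == CODE_NOISE)])

    starts_all: list[np.ndarray] = []
    for run_start, run_stop in contiguous_valid_runs(fs.valid_mask):
        starts_all.append(window_starts(run_start, run_stop, w, step))
    starts = np.concatenate(starts_all) if starts_all else np.zeros(0, dtype=int)

    n_win = len(starts)
    windows = np.empty((n_win, w, N_FEATURES), dtype=float)
    labels = np.full(n_win, CODE_UNLABELED, dtype=np.int8)
    for i, s in enumerate(starts):
        windows[i] = fs.values[s : s + w]
        nb = is_b[s + w] - is_b[s]
        nn = is_n[s + w] - is_n[s]
        if nn == 0 and nb >= PURITY * w:
            labels[i] = CODE_BREATHING
        elif nb == 0 and nn >= PURITY * w:
            labels[i] = CODE_NOISE

    return WindowSet(
        windows=windows,
        labels=labels,
        subject_ids=np.full(n_win, fs.subject_id, dtype=object),
        start_indices=np.asarray(starts, dtype=np.int64),
        window_size=w,
        step=step,
        sampling_rate_hz=fs.sampling_rate_hz,
    )


def compute_class_weights(n_breathing: int, n_noise: int) -> ClassWeightSummary:
    """Balanced weights for the two classes.

    Satisfies the conservation identity
    ``n_breathing·w_breathing + n_noise·w_noise = n_total`` exactly.
    """
    if n_breathing <= 0 or n_noise <= 0:
        raise DegenerateDataError(
            f"both classes must be present (breathing={n_breathing}, noise={n_noise})"
        )
    n_total = n_breathing + n_noise
    n_classes = 2
    return ClassWeightSummary(
        n_total=n_total,
        n_breathing=n_breathing,
        n_noise=n_noise,
        weight_breathing=n_total / (n_classes * n_breathing),
        weight_noise=n_total / (n_classes * n_noise),
    )
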