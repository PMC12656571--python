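"""From window probabilities to breathing segments and phase durations.

Rule-based post-processing of the classifier output: probabilities are
binarized at a threshold, smoothed with a short moving-average filter,
short isolated activations are suppressed, and surviving runs of breathing
windows are merged into continuous segments.  Within each segment the
squared magnitude of the Euler vector, x² + y² + z², is smoothed (0.5 s
moving average) and its alternating extrema delimit the phases: by the
default polarity, maxima mark the end of exhalation and minima the end of
inhalation, so each peak→minimum interval is an inhalation and each
minimum→peak interval an exhalation.  Per-segment means of these durations
give the mean inhalation, exhalation and total cycle times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_io import AnnotationTrack, ImuRecording, PipelineConfig
from .crnn_model import TrainedModel, predict_proba
from .features import apply_norm, engineer_features
from .windowing import make_windows

INHALE = "inhale"
EXHALE = "exhale"


@dataclass
class PredictionTrack:
    """Per-window probabilities and post-smoothing binary decisions."""

    start_times_s: np.ndarray
    probabilities: np.ndarray
    decisions: np.ndarray
    window_size_s: float
    step_s: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.start_times_s) <= 0):
            raise ValueError("window start times must be strictly increasing")


@dataclass
class Phase:
    kind: str  # INHALE or EXHALE
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BreathSegment:
    onset_s: float
    offset_s: float
    phases: list[Phase] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def breath_count(self) -> int:
        """Complete inhale+exhale pairs (non-overlapping, in phase order)."""
        count = 0
        i = 0
        while i < len(self.phases) - 1:
            if self.phases[i].kind == INHALE and self.phases[i + 1].kind == EXHALE:
                count += 1
                i += 2
            else:
                i += 1
        return count


@dataclass
class SegmentSummary:
    segment: int
    breaths: int
    mean_inhale_s: float
    mean_exhale_s: float

    @property
    def mean_cycle_s(self) -> float:
        # additive by construction: cycle = inhale + exhale
        return self.mean_inhale_s + self.mean_exhale_s


@dataclass
class BreathReport:
    summaries: list[SegmentSummary]
    n_zero_breath_segments: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment": s.segment,
                    "breaths": s.breaths,
                    "inhalation_s": s.mean_inhale_s,
                    "exhalation_s": s.mean_exhale_s,
                    "breathing_duration_s": s.mean_cycle_s,
                }
                for s in self.summaries
            ]
        )


def euler_norm_sq(x, y, z):
    """Squared magnitude x² + y² + z² of the Euler vector.

    The square root is deliberately omitted: extremum timing is invariant
    under the monotone square, and the squared form is cheaper.
    """
    x, y, z = np.asarray(x, dtype=float), np.asarray(y, dtype=float), np.asarray(z, dtype=float)
    return x * x + y * y + z * z


def _centered_moving_average(x: np.ndarray, length: int) -> np.ndarray:
    """Centered moving average whose window shrinks at the edges."""
    if length <= 1 or len(x) == 0:
        return np.asarray(x, dtype=float)
    half_left = (length - 1) // 2
    half_right = length - 1 - half_left
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half_left, 0)
    hi = np.minimum(idx + half_right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_decisions(
    probs: np.ndarray,
    threshold: float = 0.5,
    smoothing_len: int = 5,
    min_run: int = 3,
) -> np.ndarray:
    """Binarize → moving-average smooth → re-binarize → suppress short runs.

    Probabilities are binarized at ``threshold`` (ties count as breathing),
    the binary sequence is smoothed with a centered, edge-shrunk moving
    average of ``smoothing_len`` windows and re-binarized at 0.5 (ties again
    to breathing), then any run of ones shorter than ``min_run`` windows is
    zeroed.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return np.zeros(0, dtype=int)
    binary = (probs >= threshold).astype(float)
    smoothed = _centered_moving_average(binary, smoothing_len)
    decisions = (smoothed >= 0.5).astype(int)
    for run_start, run_stop in _one_runs(decisions):
        if run_stop - run_start < min_run:
            decisions[run_start:run_stop] = 0
    return decisions


def _one_runs(decisions: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[0], decisions, [0]])
    edges = np.flatnonzero(np.diff(padded))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def merge_segments(
    decisions: np.ndarray,
    window_starts_s: np.ndarray,
    window_size_s: float,
    step_s: float | None = None,
) -> list[BreathSegment]:
    """Merge maximal runs of breathing windows into continuous segments.

    Each segment spans from its first window's start to its last window's
    start plus the window duration (windows claim their full span).  A jump
    in consecutive start times larger than the stride (a gap in the
    recording) always terminates a run, so segments never span gaps.
    """
    decisions = np.asarray(decisions, dtype=int)
    starts = np.asarray(window_starts_s, dtype=float)
    if len(decisions) != len(starts):
        raise ValueError("decisions and window starts disagree in length")
    if step_s is None and len(starts) >= 2:
        step_s = float(np.min(np.diff(starts)))
    segments: list[BreathSegment] = []
    run_first: int | None = None
    for i in range(len(decisions)):
        contiguous = (
            i > 0
            and decisions[i - 1] == 1
            and step_s is not None
            and starts[i] - starts[i - 1] <= step_s * 1.5
        )
        if decisions[i] == 1 and run_first is None:
            run_first = i
        elif decisions[i] == 1 and not contiguous:
            segments.append(BreathSegment(starts[run_first], starts[i - 1] + window_size_s))
            run_first = i
        elif decisions[i] == 0 and run_first is not None:
            segments.append(BreathSegment(starts[run_first], starts[i - 1] + window_size_s))
            run_first = None
    if run_first is not None:
        segments.append(BreathSegment(starts[run_first], starts[-1] + window_size_s))
    return segments


def _alternating_extrema(
    signal: np.ndarray, fs: float, min_separation_s: float = 1.0, prominence_frac: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and kinds (+1 max, −1 min) of alternating extrema.

    Maxima and minima are located independently (minimum separation 1 s, a
    physiological half-cycle floor; prominence at least ``prominence_frac``
    of the signal's standard deviation), merged, and de-conflicted: of any
    two adjacent extrema of the same kind the more extreme one is kept, so
    ripple cannot create phantom breaths.
    """
    distance = max(1, int(round(min_separation_s * fs)))
    prominence = prominence_frac * float(np.std(signal))
    maxima, _ = find_peaks(signal, distance=distance, prominence=prominence)
    minima, _ = find_peaks(-signal, distance=distance, prominence=prominence)
    idx = np.concatenate([maxima, minima])
    kind = np.concatenate([np.ones(len(maxima), dtype=int), -np.ones(len(minima), dtype=int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]

    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = (k == 1 and signal[i] > signal[prev]) or (k == -1 and signal[i] < signal[prev])
            if better:
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    return np.asarray(keep_idx, dtype=int), np.asarray(keep_kind, dtype=int)


def detect_phases(
    rec: ImuRecording,
    segment: BreathSegment,
    norm_smooth_s: float = 0.5,
    polarity: str = "standard",
) -> BreathSegment:
    """Populate a segment with alternating inhalation/exhalation phases.

    The squared Euler magnitude over the segment is smoothed with a
    ``norm_smooth_s`` centered moving average; alternating extrema of the
    smoothed signal delimit the phases.  With the default polarity, maxima
    end exhalation and minima end inhalation (peak→minimum = inhalation);
    ``polarity="inverted"`` swaps the roles for sensors mounted the other
    way.  Partial phases before the first and after the last extremum are
    discarded; with fewer than two extrema the segment carries no phases.
    """
    if polarity not in ("standard", "inverted"):
        raise ValueError("polarity must be 'standard' or 'inverted'")
    fs = rec.sampling_rate_hz
    i0 = max(0, int(round(segment.onset_s * fs)))
    i1 = min(rec.n_samples, int(round(segment.offset_s * fs)))
    e = rec.euler[i0:i1]
    sig = euler_norm_sq(e[:, 0], e[:, 1], e[:, 2])
    sig = _centered_moving_average(sig, max(1, int(round(norm_smooth_s * fs))))
    idx, kind = _alternating_extrema(sig, fs)

    phases: list[Phase] = []
    inhale_starts_at = 1 if polarity == "standard" else -1  # extremum kind that starts an inhale
    for j in range(len(idx) - 1):
        t_a = segment.onset_s + idx[j] / fs
        t_b = segment.onset_s + idx[j + 1] / fs
        phases.append(Phase(INHALE if kind[j] == inhale_starts_at else EXHALE, t_a, t_b))
    return BreathSegment(segment.onset_s, segment.offset_s, phases)


def summarize(segments: list[BreathSegment]) -> BreathReport:
    """Per-segment breath counts and mean phase durations.

    Segments without a complete breath are excluded from the report body and
    counted in ``n_zero_breath_segments``.  The mean cycle duration is the
    sum of the mean inhalation and exhalation durations by construction.
    """
    summaries = []
    n_zero = 0
    for i, seg in enumerate(segments, start=1):
        inhales = [p.duration_s for p in seg.phases if p.kind == INHALE]
        exhales = [p.duration_s for p in seg.phases if p.kind == EXHALE]
        if seg.breath_count == 0 or not inhales or not exhales:
            n_zero += 1
            continue
        summaries.append(
            SegmentSummary(
                segment=i,
                breaths=seg.breath_count,
                mean_inhale_s=float(np.mean(inhales)),
                mean_exhale_s=float(np.mean(exhales)),
            )
        )
    return BreathReport(summaries, n_zero_breath_segments=n_zero)


def classify_recording(
    model: TrainedModel, rec: ImuRecording, cfg: PipelineConfig
) -> PredictionTrack:
    """Window a recording, score it with the model, and smooth the decisions."""
    fs = engineer_features(rec)
    ws = make_windows(fs, AnnotationTrack([]), cfg)
    if len(ws) == 0:
        return PredictionTrack(
            np.zeros(0), np.zeros(0), np.zeros(0, dtype=int),
            cfg.window_size / rec.sampling_rate_hz, cfg.step / rec.sampling_rate_hz,
        )
    x = ws.windows
    if model.norm_stats is not None:
        x = apply_norm(x, model.norm_stats)
    probs = predict_proba(model, x, batch_size=cfg.batch_size)
    decisions = smooth_decisions(probs, cfg.threshold, cfg.smoothing_len, cfg.min_run)
    return PredictionTrack(
        start_times_s=ws.start_times_s,
        probabilities=probs,
        decisions=decisions,
        window_size_s=cfg.window_size / rec.sampling_rate_hz,
        step_s=cfg.step / rec.sampling_rate_hz,
    )


def segment_recording(
    model: TrainedModel,
    rec: ImuRecording,
    cfg: PipelineConfig,
    polarity: str = "standard",
) -> tuple[PredictionTrack, list[BreathSegment], BreathReport]:
    """Full post-classification pipeline on one recording."""
    track = classify_recording(model, rec, cfg)
    segments = merge_segments(track.decisions, track.start_times_s, track.window_size_s, track.step_s)
    segments = [
        detect_phases(rec, seg, norm_smooth_s=cfg.norm_smooth_s, polarity=polarity)
        for seg in segments
    ]
    return track, segments, summarize(segments)
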