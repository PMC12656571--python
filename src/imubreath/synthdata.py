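"""Synthetic abdominal-IMU recordings with ground-truth breathing phases.

The generator emulates a two-part wearable protocol: quiet standing with
quasi-periodic abdominal breathing (cycle length around 3–5 s, distinct
inhale/exhale slopes) and walking episodes whose motion swamps the
respiratory oscillation (labeled noise), separated by unlabeled transition
spans, with optional mid-recording signal gaps.

Breathing waveform
------------------
Each cycle is a piecewise raised cosine: during inhalation the signal
descends from +A to −A over ``ie_ratio``·period, during exhalation it rises
back over the remainder.  Minima therefore mark the end of inhalation and
maxima the end of exhalation, matching the downstream phase-detection
convention, and the inhale/exhale asymmetry is controlled by ``ie_ratio``.
The oscillation is injected predominantly into the Euler channels (abdominal
wall inclination) with a weaker echo in the accelerations.

Gait noise is band-limited Gaussian motion (default 1.5–2.5 Hz, the stride
band of normal walking) plus step-like baseline shifts; it contains no
stable energy at respiratory frequencies, which is what makes the two
classes separable when sensor noise is low.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .core_io import (
    LABEL_BREATHING,
    LABEL_NOISE,
    AnnotationTrack,
    ImuRecording,
    Interval,
    write_annotations,
    write_recording,
)
from .errors import ConfigError

INHALE_START = "inhale_start"
EXHALE_START = "exhale_start"

#: Fixed per-channel mixing of the unit breathing waveform into (euler, acc).
_EULER_MIX = np.array([1.0, 0.35, 0.2])
_ACC_MIX = np.array([0.8, 0.4, 1.0])
_EULER_BASELINE = np.array([25.0, 8.0, 5.0])  # degrees; keeps the norm-signal polarity stable


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Span layout: ``breathing_spans``, ``noise_episodes`` and ``gap_spans`` are
    lists of ``(start_s, end_s)`` and must not overlap each other; time covered
    by none of them is unlabeled.  When spans are left as ``None`` a default
    protocol is laid out as fractions of the duration: one long breathing span
    (4–46%), two gait episodes (54–71% and 79–96%), unlabeled transitions in
    between — mimicking a static breathing test followed by walking trials
    with imperfectly synchronized annotation.
    """

    duration_s: float = 240.0
    sampling_rate_hz: float = 330.0
    breath_period_mean_s: float = 4.0
    breath_period_sd_s: float = 0.3
    ie_ratio: float = 0.6
    breath_amp_deg: float = 5.0
    breath_amp_acc: float = 0.3
    breathing_spans: list[tuple[float, float]] | None = None
    noise_episodes: list[tuple[float, float]] | None = None
    gait_amp_deg: float = 8.0
    gait_amp_acc: float = 1.5
    gait_band_hz: tuple[float, float] = (1.5, 2.5)
    sensor_noise_sd: float = 0.05
    gap_spans: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ie_ratio < 1.0:
            raise ConfigError("ie_ratio must be in (0, 1)")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigError("duration_s and sampling_rate_hz must be positive")
        if self.breathing_spans is None:
            d = self.duration_s
            self.breathing_spans = [(0.04 * d, 0.46 * d)]
        if self.noise_episodes is None:
            d = self.duration_s
            self.noise_episodes = [(0.54 * d, 0.71 * d), (0.79 * d, 0.96 * d)]
        self._validate_spans()

    def _validate_spans(self) -> None:
        tagged = (
            [(s, e, "breathing") for s, e in self.breathing_spans]
            + [(s, e, "noise") for s, e in self.noise_episodes]
            + [(s, e, "gap") for s, e in self.gap_spans]
        )
        for s, e, kind in tagged:
            if not 0.0 <= s < e <= self.duration_s + 1e-9:
                raise ConfigError(f"{kind} span ({s}, {e}) outside [0, {self.duration_s}]")
        tagged.sort()
        for (s0, e0, k0), (s1, e1, k1) in zip(tagged, tagged[1:]):
            if s1 < e0 - 1e-9:
                raise ConfigError(f"overlapping spans: {k0} ({s0}, {e0}) and {k1} ({s1}, {e1})")

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class SpanStats:
    """Ground-truth phase durations of the complete cycles inside one breathing span."""

    start_s: float
    end_s: float
    n_cycles: int
    true_mean_inhale_s: float
    true_mean_exhale_s: float

    @property
    def true_mean_cycle_s(self) -> float:
        return self.true_mean_inhale_s + self.true_mean_exhale_s


@dataclass
class GroundTruth:
    annotation: AnnotationTrack
    phase_events: list[tuple[float, str]]
    span_stats: list[SpanStats]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phase_events": [[t, kind] for t, kind in self.phase_events],
            "span_stats": [dataclasses.asdict(s) for s in self.span_stats],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _breathing_waveform(
    rng: np.random.Generator, span_s: float, spec: SyntheticSpec
) -> tuple[np.ndarray, list[tuple[float, str]], SpanStats]:
    """Unit-amplitude waveform for one breathing span plus its ground truth.

    Cycle periods are drawn i.i.d. from N(mean, sd), floored at 1 s.  Cycles
    are generated until the span is tiled; the trailing partial cycle is
    truncated and excluded from the per-span duration statistics.
    """
    fs = spec.sampling_rate_hz
    n = int(round(span_s * fs))
    t = np.arange(n) / fs
    x = np.full(n, 1.0)
    events: list[tuple[float, str]] = []
    inhales: list[float] = []
    exhales: list[float] = []
    t0 = 0.0
    while t0 < span_s:
        period = max(1.0, rng.normal(spec.breath_period_mean_s, spec.breath_period_sd_s))
        ti = spec.ie_ratio * period
        te = period - ti
        sel_in = (t >= t0) & (t < t0 + ti)
        x[sel_in] = np.cos(np.pi * (t[sel_in] - t0) / ti)
        sel_ex = (t >= t0 + ti) & (t < t0 + period)
        x[sel_ex] = -np.cos(np.pi * (t[sel_ex] - t0 - ti) / te)
        events.append((t0, INHALE_START))
        if t0 + ti < span_s:
            events.append((t0 + ti, EXHALE_START))
        if t0 + period <= span_s:
            inhales.append(ti)
            exhales.append(te)
        t0 += period
    stats = SpanStats(
        start_s=0.0,
        end_s=span_s,
        n_cycles=len(inhales),
        true_mean_inhale_s=float(np.mean(inhales)) if inhales else float("nan"),
        true_mean_exhale_s=float(np.mean(exhales)) if exhales else float("nan"),
    )
    return x, events, stats


def _gait_noise(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> np.ndarray:
    """Unit-variance band-limited motion with step-like baseline drift, shape (n,)."""
    fs = spec.sampling_rate_hz
    lo, hi = spec.gait_band_hz
    nyq = fs / 2.0
    white = rng.standard_normal(n + int(4 * fs))  # pad to wash out filter transients
    if hi < nyq * 0.95:
        sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        band = sp_signal.sosfiltfilt(sos, white)[int(2 * fs) : int(2 * fs) + n]
    else:  # band collides with Nyquist at very low sampling rates: high-pass only
        sos = sp_signal.butter(4, lo, btype="highpass", fs=fs, output="sos")
        band = sp_signal.sosfiltfilt(sos, white)[int(2 * fs) : int(2 * fs) + n]
    band = band / max(band.std(), 1e-12)
    # one baseline step per ~second, as in postural shifts during walking
    n_steps = max(1, int(n / fs))
    step_times = rng.integers(0, n, size=n_steps)
    steps = np.zeros(n)
    steps[step_times] += rng.normal(0.0, 0.3, size=n_steps)
    return band + np.cumsum(steps)


def simulate_recording(spec: SyntheticSpec) -> tuple[ImuRecording, GroundTruth]:
    """Generate one labeled recording with ground-truth breathing phases.

    Deterministic: the same spec (including its seed) always yields a
    bit-identical recording.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    euler = np.tile(_EULER_BASELINE, (n, 1))
    acc = np.zeros((n, 3))
    events: list[tuple[float, str]] = []
    span_stats: list[SpanStats] = []
    intervals: list[Interval] = []

    for start_s, end_s in spec.breathing_spans:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        wave, span_events, stats = _breathing_waveform(rng, (i1 - i0) / fs, spec)
        wave = wave[: i1 - i0]
        euler[i0:i1] += np.outer(wave, _EULER_MIX) * spec.breath_amp_deg
        acc[i0:i1] += np.outer(wave, _ACC_MIX) * spec.breath_amp_acc
        events.extend((start_s + ts, kind) for ts, kind in span_events)
        stats.start_s, stats.end_s = start_s, end_s
        span_stats.append(stats)
        intervals.append(Interval(start_s, end_s, LABEL_BREATHING))

    for start_s, end_s in spec.noise_episodes:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        for j in range(3):
            euler[i0:i1, j] += _gait_noise(rng, i1 - i0, spec) * spec.gait_amp_deg * _EULER_MIX[j]
            acc[i0:i1, j] += _gait_noise(rng, i1 - i0, spec) * spec.gait_amp_acc * _ACC_MIX[j]
        intervals.append(Interval(start_s, end_s, LABEL_NOISE))

    euler += rng.normal(0.0, spec.sensor_noise_sd, size=(n, 3))
    acc += rng.normal(0.0, spec.sensor_noise_sd, size=(n, 3))

    valid = np.ones(n, dtype=bool)
    for start_s, end_s in spec.gap_spans:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        valid[i0:i1] = False
        euler[i0:i1] = 0.0
        acc[i0:i1] = 0.0

    rec = ImuRecording(
        subject_id=f"synthetic-{spec.seed}",
        sampling_rate_hz=fs,
        euler=euler,
        acc=acc,
        valid_mask=valid,
    )
    gt = GroundTruth(
        annotation=AnnotationTrack(intervals),
        phase_events=sorted(events),
        span_stats=span_stats,
    )
    return rec, gt


def simulate_cohort(
    n_subjects: int, template: SyntheticSpec, seed: int = 0
) -> list[tuple[ImuRecording, GroundTruth]]:
    """Simulate ``n_subjects`` recordings with per-subject parameter draws.

    Each subject gets an independent child seed, a mean breath period drawn
    from N(template mean, template sd) floored at 2 s, and amplitude jitter
    (±20%), so between-subject variability is present even when every
    recording shares the template's span layout.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        subj_seed = int(rng.integers(0, 2**31 - 1))
        subj_rng = np.random.default_rng(subj_seed)
        period = max(2.0, subj_rng.normal(template.breath_period_mean_s, template.breath_period_sd_s))
        amp_jitter = subj_rng.uniform(0.8, 1.2)
        spec = template.replace(
            breath_period_mean_s=period,
            breath_amp_deg=template.breath_amp_deg * amp_jitter,
            breath_amp_acc=template.breath_amp_acc * amp_jitter,
            seed=subj_seed,
        )
        rec, gt = simulate_recording(spec)
        rec.subject_id = f"S{i:02d}"
        cohort.append((rec, gt))
    return cohort


def write_subject(
    out_dir: str | Path, rec: ImuRecording, gt: GroundTruth
) -> dict[str, Path]:
    """Write one subject's recording, annotation and ground-truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "recording": out_dir / f"{rec.subject_id}_recording.csv",
        "annotations": out_dir / f"{rec.subject_id}_annotations.csv",
        "ground_truth": out_dir / f"{rec.subject_id}_ground_truth.json",
    }
    write_recording(rec, paths["recording"])
    write_annotations(gt.annotation, paths["annotations"])
    gt.to_json(paths["ground_truth"])
    return paths
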