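"""Shared fixtures: small deterministic recordings and a pre-trained model.

All inputs are generated programmatically at scaled-down problem sizes
(33 Hz sampling, 100-sample ≈ 3 s windows with a 10-sample ≈ 0.3 s stride,
i.e. the nominal 330 Hz geometry divided by ten) so the full pipeline —
including network training — runs quickly while keeping the physiological
defaults (4 s breath period, 0.6 inhale fraction, 1.5–2.5 Hz gait band).
"""

import numpy as np
import pytest

import imubreath as ib
from imubreath.crnn_model import TrainConfig
from imubreath.evaluation import windows_from_cohort
from imubreath.features import apply_norm, fit_norm_stats
from imubreath.windowing import WindowSet, compute_class_weights

FS = 33.0  # Hz; scaled-down analogue of the nominal 330 Hz
SMALL_CFG = dict(window_size=100, step=10)


@pytest.fixture(scope="session")
def small_cfg() -> ib.PipelineConfig:
    return ib.PipelineConfig(window_size=100, step=10, epochs=6, seed=7)


@pytest.fixture(scope="session")
def cohort10(small_cfg):
    """Ten separable synthetic subjects (120 s each at 33 Hz)."""
    template = ib.SyntheticSpec(duration_s=120.0, sampling_rate_hz=FS)
    return ib.simulate_cohort(10, template, seed=7)


@pytest.fixture(scope="session")
def balanced_cohort():
    """Ten subjects with equal breathing and noise time (class prior ≈ 0.5)."""
    template = ib.SyntheticSpec(
        duration_s=120.0,
        sampling_rate_hz=FS,
        breathing_spans=[(5.0, 55.0)],
        noise_episodes=[(60.0, 110.0)],
    )
    return ib.simulate_cohort(10, template, seed=21)


@pytest.fixture(scope="session")
def trained_small_model(small_cfg):
    """A classifier trained on four synthetic subjects (seconds, fully separable)."""
    template = ib.SyntheticSpec(duration_s=90.0, sampling_rate_hz=FS)
    cohort = ib.simulate_cohort(4, template, seed=11)
    ws = windows_from_cohort(cohort, small_cfg)
    lab = ws.select(ws.labeled_mask)
    stats = fit_norm_stats(lab.windows, fitted_on="trained_small_model fixture")
    x = apply_norm(lab.windows, stats)
    lab_norm = WindowSet(
        x, lab.labels, lab.subject_ids, lab.start_indices,
        lab.window_size, lab.step, lab.sampling_rate_hz,
    )
    n_b, n_n = lab_norm.counts()
    spec = ib.ModelSpec(window_size=small_cfg.window_size)
    net = ib.build_model(spec, seed=3)
    cfg = TrainConfig(epochs=3, batch_size=32, class_weights=compute_class_weights(n_b, n_n), seed=3)
    return ib.train(net, lab_norm, None, cfg, spec=spec, norm_stats=stats)


@pytest.fixture()
def tiny_recording():
    """200 samples at 10 Hz with a 30-sample gap, deterministic content."""
    rng = np.random.default_rng(0)
    n = 200
    euler = rng.normal(20.0, 2.0, size=(n, 3))
    acc = rng.normal(0.0, 0.5, size=(n, 3))
    mask = np.ones(n, dtype=bool)
    mask[80:110] = False
    return ib.ImuRecording("T00", 10.0, euler, acc, mask)
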