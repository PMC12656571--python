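"""The 1D convolutional-recurrent breathing classifier.

Architecture (fixed defaults): two valid 1-D convolutions (32 then 64
filters, kernel 5), each followed by max pooling of size 2, an LSTM with 64
units whose final hidden state feeds — through dropout (p = 0.5) — a
32-unit ReLU dense layer and a single sigmoid output.  With 14 input
channels this stack has exactly 47,713 trainable parameters, independent of
the window length; at 32-bit precision that is about 0.18 MB of weights.

Training uses Adam (lr 0.001) on class-weighted binary cross-entropy for a
fixed number of epochs; the validation set is monitored only, never used
for early stopping.  Breathing is the positive class (label 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .core_io import CODE_BREATHING, CODE_UNLABELED
from .errors import ConfigError, DegenerateDataError
from .features import N_FEATURES, NormStats
from .windowing import ClassWeightSummary, WindowSet

BYTES_PER_PARAM_32BIT = 4


@dataclass
class ModelSpec:
    """Architecture hyperparameters (defaults are the published configuration)."""

    in_channels: int = N_FEATURES
    conv1_filters: int = 32
    conv1_kernel: int = 5
    conv2_filters: int = 64
    conv2_kernel: int = 5
    pool_size: int = 2
    lstm_units: int = 64
    dropout_p: float = 0.5
    dense_units: int = 32
    window_size: int = 2000

    def __post_init__(self) -> None:
        for name in ("in_channels", "conv1_filters", "conv2_filters", "lstm_units", "dense_units"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def sequence_lengths(self) -> tuple[int, int, int, int]:
        """Time lengths after conv1, pool1, conv2, pool2 (valid convolutions)."""
        l1 = self.window_size - self.conv1_kernel + 1
        p1 = l1 // self.pool_size
        l2 = p1 - self.conv2_kernel + 1
        p2 = l2 // self.pool_size
        return l1, p1, l2, p2

    def validate_window(self) -> None:
        l1, p1, l2, p2 = self.sequence_lengths()
        if min(l1, p1, l2, p2) < 1:
            raise ConfigError(
                f"window_size {self.window_size} too small for two valid convolutions + pooling"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    class_weights: ClassWeightSummary | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: nn.Sequential
    norm_stats: NormStats | None
    history: dict[str, list[float]] = field(default_factory=dict)
    train_config: TrainConfig | None = None


def count_trainable_parameters(spec: ModelSpec) -> int:
    """Closed-form parameter count; independent of the window length.

    conv: (in·k + 1)·filters, LSTM: 4·((in + units)·units + units),
    dense: in·units + units, output: dense_units + 1.
    """
    conv1 = (spec.in_channels * spec.conv1_kernel + 1) * spec.conv1_filters
    conv2 = (spec.conv1_filters * spec.conv2_kernel + 1) * spec.conv2_filters
    lstm = 4 * ((spec.conv2_filters + spec.lstm_units) * spec.lstm_units + spec.lstm_units)
    dense = spec.lstm_units * spec.dense_units + spec.dense_units
    out = spec.dense_units + 1
    return conv1 + conv2 + lstm + dense + out


def memory_footprint_mb(spec: ModelSpec, bytes_per_param: int = BYTES_PER_PARAM_32BIT) -> float:
    """Weight-storage footprint in binary megabytes."""
    return count_trainable_parameters(spec) * bytes_per_param / 2**20


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the layer stack with seeded initialization.

    Raises ConfigError if the window is too short to survive both valid
    convolutions and poolings.
    """
    spec.validate_window()
    rng = np.random.default_rng(seed)
    net = nn.Sequential(
        [
            nn.Conv1D(spec.in_channels, spec.conv1_filters, spec.conv1_kernel, rng, "conv1"),
            nn.MaxPool1D(spec.pool_size),
            nn.Conv1D(spec.conv1_filters, spec.conv2_filters, spec.conv2_kernel, rng, "conv2"),
            nn.MaxPool1D(spec.pool_size),
            nn.LSTM(spec.conv2_filters, spec.lstm_units, rng, "lstm"),
            nn.Dropout(spec.dropout_p, rng),
            nn.Dense(spec.lstm_units, spec.dense_units, rng, "dense", relu=True),
            nn.Dense(spec.dense_units, 1, rng, "out"),
        ]
    )
    assert net.n_parameters() == count_trainable_parameters(spec)
    return net


def _labeled_xy(ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    mask = ws.labels != CODE_UNLABELED
    return ws.windows[mask], (ws.labels[mask] == CODE_BREATHING).astype(float)


def train(
    net: nn.Sequential,
    train_windows: WindowSet,
    val_windows: WindowSet | None,
    cfg: TrainConfig,
    spec: ModelSpec | None = None,
    norm_stats: NormStats | None = None,
) -> TrainedModel:
    """Fixed-epoch training with per-class loss weighting.

    Unlabeled windows are dropped.  The history records the mean (weighted)
    training loss and the unweighted validation loss per epoch; with a fixed
    seed on fixed data the run is bit-reproducible.
    """
    x, y = _labeled_xy(train_windows)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set must contain both classes")
    if cfg.class_weights is not None:
        weights = np.where(y == 1.0, cfg.class_weights.weight_breathing, cfg.class_weights.weight_noise)
    else:
        weights = np.ones(len(y))

    xv = yv = None
    if val_windows is not None and len(val_windows):
        xv, yv = _labeled_xy(val_windows)
        if len(xv) == 0:
            xv = yv = None

    rng = np.random.default_rng(cfg.seed)
    # reseed dropout so training is a pure function of (data, cfg.seed)
    for layer in net.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    opt = nn.Adam(net.params(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    for _ in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for lo in range(0, len(x), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(x[idx], train=True)
            loss, dlogits = nn.bce_with_logits(logits, y[idx], weights[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if xv is not None:
            probs = net.predict_proba(xv, batch_size=cfg.batch_size)
            eps = 1e-12
            val_loss = float(-np.mean(yv * np.log(probs + eps) + (1 - yv) * np.log(1 - probs + eps)))
            history["val_loss"].append(val_loss)

    return TrainedModel(spec=spec, net=net, norm_stats=norm_stats, history=history, train_config=cfg)


def predict_proba(model: "TrainedModel | nn.Sequential", windows: "WindowSet | np.ndarray",
                  batch_size: int = 32) -> np.ndarray:
    """Breathing-class probability per window, in input order."""
    net = model.net if isinstance(model, TrainedModel) else model
    x = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows, dtype=float)
    if x.ndim != 3 or x.shape[2] != net.layers[0].W.value.shape[1]:
        raise ValueError(f"expected (n, w, {net.layers[0].W.value.shape[1]}) windows; got {x.shape}")
    return net.predict_proba(x, batch_size=batch_size)


# ---------------------------------------------------------------------------
# Bundle serialization (weights + spec + normalization statistics together)


def save_bundle(model: TrainedModel, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "weights.npz", **model.net.get_weights())
    spec = model.spec or ModelSpec()
    (out_dir / "spec.json").write_text(json.dumps(spec.to_dict(), indent=1))
    if model.norm_stats is not None:
        model.norm_stats.to_json(out_dir / "norm_stats.json")
    (out_dir / "history.json").write_text(json.dumps(model.history, indent=1))
    return out_dir


def load_bundle(bundle_dir: str | Path) -> TrainedModel:
    """Load a saved model; the parameter count is re-verified against the spec."""
    bundle_dir = Path(bundle_dir)
    spec = ModelSpec(**json.loads((bundle_dir / "spec.json").read_text()))
    net = build_model(spec, seed=0)
    with np.load(bundle_dir / "weights.npz") as data:
        net.set_weights({k: data[k] for k in data.files})
    if net.n_parameters() != count_trainable_parameters(spec):
        raise ConfigError("bundle weight count does not match its architecture spec")
    stats_path = bundle_dir / "norm_stats.json"
    norm_stats = NormStats.from_json(stats_path) if stats_path.exists() else None
    history = {}
    hist_path = bundle_dir / "history.json"
    if hist_path.exists():
        history = json.loads(hist_path.read_text())
    return TrainedModel(spec=spec, net=net, norm_stats=norm_stats, history=history)
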