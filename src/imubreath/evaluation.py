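"""Subject-grouped cross-validation, binary metrics, and window-size sweeps.

All evaluation is subject-independent: every subject's windows live in
exactly one test fold, and both the normalization statistics and the class
weights are fitted on each fold's training windows only, so no information
leaks from test subjects into the fitted pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CODE_BREATHING, PipelineConfig
from .crnn_model import ModelSpec, TrainConfig, build_model, predict_proba, train
from .errors import DegenerateDataError
from .features import apply_norm, engineer_features, fit_norm_stats
from .windowing import WindowSet, compute_class_weights, make_windows


@dataclass
class FoldResult:
    fold_id: int
    test_subjects: list[str]
    tp: int
    fp: int
    fn: int
    tn: int
    metrics: dict[str, float | None]
    class_weights: tuple[float, float]  # (breathing, noise) used for training

    @property
    def n_test_windows(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SweepReport:
    """Mean ± sd of each metric over folds, per window size."""

    rows: dict[int, dict[str, tuple[float, float]]] = field(default_factory=dict)
    n_splits: int = 5

    def to_frame(self) -> pd.DataFrame:
        records = []
        for w, stats in sorted(self.rows.items()):
            rec = {"window_size": w}
            for metric, (mean, sd) in stats.items():
                rec[f"{metric}_mean"] = mean
                rec[f"{metric}_sd"] = sd
            records.append(rec)
        return pd.DataFrame(records)


def group_kfold_split(
    subject_ids: np.ndarray, n_splits: int = 5, seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray, list[str]]]:
    """Grouped k-fold assignments at subject granularity.

    Subjects are sorted by descending window count (ties shuffled by the
    seed) and dealt round-robin to folds, balancing fold sizes.  Returns one
    ``(train_idx, test_idx, test_subjects)`` triple per fold; train and test
    subject sets are disjoint by construction.
    """
    subject_ids = np.asarray(subject_ids)
    subjects, counts = np.unique(subject_ids, return_counts=True)
    if len(subjects) < n_splits:
        raise DegenerateDataError(
            f"{len(subjects)} subjects cannot populate {n_splits} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    order = order[np.argsort(-counts[order], kind="stable")]
    fold_of = {subjects[j]: i % n_splits for i, j in enumerate(order)}

    folds = []
    window_fold = np.array([fold_of[s] for s in subject_ids])
    for k in range(n_splits):
        test_idx = np.flatnonzero(window_fold == k)
        train_idx = np.flatnonzero(window_fold != k)
        test_subjects = sorted(s for s, f in fold_of.items() if f == k)
        assert not set(subject_ids[train_idx]) & set(subject_ids[test_idx])
        folds.append((train_idx, test_idx, test_subjects))
    return folds


def f1_score(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean 2PR/(P+R); absent when either input is absent or both are 0."""
    if precision is None or recall is None or (precision + recall) == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float | None]:
    """Accuracy, precision, recall, F1 with breathing as the positive class.

    Ratios with a zero denominator are reported as ``None`` (absent), not 0.
    """
    total = tp + fp + fn + tn
    if total == 0:
        raise DegenerateDataError("empty confusion matrix")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1_score(precision, recall),
    }


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def windows_from_cohort(cohort, cfg: PipelineConfig) -> WindowSet:
    """Engineer features and window every recording of a cohort (unnormalized)."""
    parts = []
    for rec, gt in cohort:
        fs = engineer_features(rec)
        parts.append(make_windows(fs, gt.annotation, cfg))
    return WindowSet.concatenate(parts)


def run_cv(
    cohort,
    cfg: PipelineConfig,
    spec: ModelSpec | None = None,
    n_splits: int = 5,
    threshold: float | None = None,
    windows: WindowSet | None = None,
    label_shuffle_seed: int | None = None,
) -> list[FoldResult]:
    """Grouped cross-validation of the full pipeline on a cohort.

    Per fold: fit normalization statistics and class weights on the training
    windows only, train a freshly initialized classifier, and score the test
    windows.  Unlabeled windows never enter training or metrics.
    ``label_shuffle_seed`` permutes labels within subjects (null experiment).
    """
    if spec is None:
        spec = ModelSpec(window_size=cfg.window_size)
    if windows is None:
        windows = windows_from_cohort(cohort, cfg)
    threshold = cfg.threshold if threshold is None else threshold

    labels = windows.labels.copy()
    if label_shuffle_seed is not None:
        rng = np.random.default_rng(label_shuffle_seed)
        for subj in np.unique(windows.subject_ids):
            idx = np.flatnonzero((windows.subject_ids == subj) & windows.labeled_mask)
            labels[idx] = labels[rng.permutation(idx)]

    labeled = np.flatnonzero(labels != -1)
    folds = group_kfold_split(windows.subject_ids[labeled], n_splits=n_splits, seed=cfg.seed)

    results = []
    for fold_id, (train_rel, test_rel, test_subjects) in enumerate(folds):
        train_idx, test_idx = labeled[train_rel], labeled[test_rel]
        x_train = windows.windows[train_idx]
        y_train = (labels[train_idx] == CODE_BREATHING).astype(float)
        x_test = windows.windows[test_idx]
        y_test = (labels[test_idx] == CODE_BREATHING).astype(float)

        stats = fit_norm_stats(x_train, fitted_on=f"fold{fold_id}-train")
        x_train = apply_norm(x_train, stats)
        x_test = apply_norm(x_test, stats)

        n_b = int(y_train.sum())
        n_n = len(y_train) - n_b
        weights = compute_class_weights(n_b, n_n)

        net = build_model(spec, seed=cfg.seed + fold_id)
        tcfg = TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            class_weights=weights,
            seed=cfg.seed + 1000 + fold_id,
        )
        train_ws = WindowSet(
            x_train,
            (y_train > 0.5).astype(np.int8),
            windows.subject_ids[train_idx],
            windows.start_indices[train_idx],
            windows.window_size,
            windows.step,
            windows.sampling_rate_hz,
        )
        trained = train(net, train_ws, None, tcfg, spec=spec, norm_stats=stats)

        probs = predict_proba(trained, x_test, batch_size=cfg.batch_size)
        y_pred = (probs >= threshold).astype(int)
        tp, fp, fn, tn = confusion_from_predictions(y_test.astype(int), y_pred)
        results.append(
            FoldResult(
                fold_id=fold_id,
                test_subjects=test_subjects,
                tp=tp,
                fp=fp,
                fn=fn,
                tn=tn,
                metrics=compute_metrics(tp, fp, fn, tn),
                class_weights=(weights.weight_breathing, weights.weight_noise),
            )
        )
    return results


def run_sweep(
    cohort, window_sizes, cfg: PipelineConfig, spec: ModelSpec | None = None, n_splits: int = 5
) -> SweepReport:
    """run_cv per window size; aggregate mean ± sd of each metric over folds."""
    report = SweepReport(n_splits=n_splits)
    for w in window_sizes:
        w_cfg = dataclasses.replace(cfg, window_size=int(w))
        w_spec = ModelSpec(window_size=int(w)) if spec is None else dataclasses.replace(spec, window_size=int(w))
        folds = run_cv(cohort, w_cfg, spec=w_spec, n_splits=n_splits)
        stats = {}
        for metric in ("accuracy", "precision", "recall", "f1"):
            vals = [f.metrics[metric] for f in folds if f.metrics[metric] is not None]
            stats[metric] = (float(np.mean(vals)), float(np.std(vals))) if vals else (float("nan"),) * 2
        report.rows[int(w)] = stats
    return report


def fold_results_frame(results: list[FoldResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fold": r.fold_id,
                "test_subjects": ";".join(r.test_subjects),
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "accuracy": r.metrics["accuracy"],
                "precision": r.metrics["precision"],
                "recall": r.metrics["recall"],
                "f1": r.metrics["f1"],
                "weight_breathing": r.class_weights[0],
                "weight_noise": r.class_weights[1],
            }
            for r in results
        ]
    )
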