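"""Evaluation metrics, the binary-task protocol, stratified k-fold CV and
end-to-end experiment orchestration.

The primary protocol is stratified k-fold cross-validation (default 25
folds) over one of the four binary tasks — normal vs one stroke stage, the
stroke stage being the positive class so that recall reads as stroke
sensitivity — or over all five classes with one-vs-rest macro averaging.
Metrics are accuracy, precision, recall, F1 and AUC (rank-sum / Mann-
Whitney formulation with midranks for ties). Wall time per configuration is
reported informationally, never asserted.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ctstroke import core_io
from ctstroke.core_io import SampleRecord, StrokeStage, STROKE_STAGES
from ctstroke.edrvfl import EdRVFLConfig, fit, init_model, predict, predict_scores
from ctstroke.features import BlockStatExtractor, FeatureExtractor, extract_matrix
from ctstroke.spem import SPEMConfig

__all__ = [
    "MetricsReport",
    "RunConfig",
    "binary_task",
    "compute_metrics",
    "kfold_split",
    "cross_validate",
    "run_experiment",
]

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.10g"  # fixed format so reruns are byte-identical


@dataclass
class MetricsReport:
    """One row of the evaluation table (per fold or aggregate)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    n_samples: int
    task: str = ""
    fold: int | None = None
    wall_time_s: float = 0.0
    degenerate: bool = False  # some ratio had a zero denominator


@dataclass
class RunConfig:
    """Configuration of one experiment run.

    ``task`` is ``"normal_vs_<stage>"`` for the four binary groups or
    ``"multiclass"`` for all five stages; ``spem`` may be a single
    :class:`SPEMConfig`, ``None`` (raw images), or ``"both"`` for a paired
    raw-vs-enhanced comparison in one invocation. The 70/20/10 fixed split
    of the source protocol is available as ``cv_folds=0`` with
    ``split`` proportions; k-fold CV is the primary protocol.
    """

    manifest: Path | str = "manifest.csv"
    task: str = "normal_vs_chronic"
    spem: SPEMConfig | None | str = None
    extractor: FeatureExtractor | None = None
    edrvfl: EdRVFLConfig = field(default_factory=EdRVFLConfig)
    cv_folds: int = 25
    split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    augment: bool = False
    seed: int = 0
    out_dir: Path | str = "."

    def __post_init__(self) -> None:
        if self.cv_folds and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2 (or 0 for the fixed split)")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


def binary_task(records: Sequence[SampleRecord], stage: StrokeStage) -> tuple[list[SampleRecord], np.ndarray]:
    """Restrict a record list to normal + one stroke stage.

    Returns the filtered records (order preserved) and their labels; the
    stroke stage is the positive class.
    """
    if stage == StrokeStage.NORMAL:
        raise ValueError("binary tasks pair normal with a stroke stage, not with itself")
    kept = [r for r in records if r.stage in (StrokeStage.NORMAL, stage)]
    n_pos = sum(r.stage == stage for r in kept)
    if n_pos == 0 or len(kept) - n_pos == 0:
        raise ValueError(f"task normal_vs_{stage.value}: both classes must be present")
    y = np.array([r.stage.value for r in kept], dtype=object)
    return kept, y


def _auc_rank(y_true: np.ndarray, scores: np.ndarray, positive: str) -> float:
    """AUC by the Mann-Whitney rank-sum formulation with midranks for ties."""
    pos = y_true == positive
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0
    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, scores: Sequence[float], positive: str
) -> MetricsReport:
    """Binary accuracy, precision, recall, F1 and AUC.

    ``scores`` are positive-class scores (used only for AUC). Ratios with a
    zero denominator are reported as 0 with the ``degenerate`` flag set, so
    a degenerate fold does not abort a run.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("y_true, y_pred and scores must have equal length")

    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))

    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = 0.0
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif tp + fp == 0 and tp + fn == 0:
        degenerate = True
    auc = _auc_rank(y_true, scores, positive)
    if degenerate:
        logger.warning("zero denominator in precision/recall; reported as 0")
    return MetricsReport(
        accuracy=(tp + tn) / len(y_true),
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        n_samples=len(y_true),
        degenerate=degenerate,
    )


def kfold_split(
    n: int, k: int, seed: int, y: Sequence | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (stratified, when ``y`` is given) k-fold partition.

    Test folds are disjoint and cover all indices exactly once. Within each
    class, indices are shuffled and dealt round-robin to folds; if some
    class has fewer than ``k`` members, stratification degrades to a plain
    shuffled split with a warning.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if y is not None:
        y = np.asarray(y, dtype=object)
        counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
        if min(counts.values()) < k:
            logger.warning("a class has fewer than %d members; falling back to a plain split", k)
            y = None
    if y is None:
        order = rng.permutation(n)
        fold_of[order] = np.arange(n) % k
    else:
        offset = 0
        for c in sorted(np.unique(y).tolist()):
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(len(idx))]
            fold_of[idx] = (offset + np.arange(len(idx))) % k
            offset += len(idx)
    folds = []
    all_idx = np.arange(n)
    for f in range(k):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        folds.append((train, test))
    return folds


def _positive_scores(model, scores: np.ndarray, positive: str) -> np.ndarray:
    return scores[:, model.classes.index(positive)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EdRVFLConfig,
    k: int,
    seed: int,
    positive: str,
    task: str = "",
) -> list[MetricsReport]:
    """k-fold CV of the edRVFL classifier; returns per-fold reports plus a
    final mean row (fold = None, metrics averaged arithmetically)."""
    folds = kfold_split(len(y), k, seed, y)
    n_classes = len(np.unique(y))
    reports: list[MetricsReport] = []
    for f, (train, test) in enumerate(folds):
        t0 = time.perf_counter()
        model = init_model(X.shape[1], n_classes, cfg)
        fit(model, X[train], y[train])
        scores = predict_scores(model, X[test])
        y_pred = predict(model, X[test])
        rep = compute_metrics(y[test], y_pred, _positive_scores(model, scores, positive), positive)
        rep.task, rep.fold = task, f
        rep.wall_time_s = time.perf_counter() - t0
        reports.append(rep)
    reports.append(_mean_report(reports, task))
    return reports


def _mean_report(fold_reports: list[MetricsReport], task: str) -> MetricsReport:
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        f1=float(np.mean([r.f1 for r in fold_reports])),
        auc=float(np.mean([r.auc for r in fold_reports])),
        n_samples=int(sum(r.n_samples for r in fold_reports)),
        task=task,
        fold=None,
        wall_time_s=float(np.sum([r.wall_time_s for r in fold_reports])),
        degenerate=any(r.degenerate for r in fold_reports),
    )


def _macro_multiclass_metrics(y_true, y_pred, scores, classes) -> MetricsReport:
    """One-vs-rest macro averaging over all five stages (extension beyond
    the four binary groups; labeled 'multiclass' in reports)."""
    per_class = []
    for ci, c in enumerate(classes):
        yt = np.where(np.asarray(y_true, dtype=object) == c, "pos", "neg")
        yp = np.where(np.asarray(y_pred, dtype=object) == c, "pos", "neg")
        per_class.append(compute_metrics(yt, yp, scores[:, ci], "pos"))
    acc = float(np.mean(np.asarray(y_true, dtype=object) == np.asarray(y_pred, dtype=object)))
    return MetricsReport(
        accuracy=acc,
        precision=float(np.mean([m.precision for m in per_class])),
        recall=float(np.mean([m.recall for m in per_class])),
        f1=float(np.mean([m.f1 for m in per_class])),
        auc=float(np.mean([m.auc for m in per_class])),
        n_samples=len(y_true),
        degenerate=any(m.degenerate for m in per_class),
    )


def _cross_validate_multiclass(X, y, cfg, k, seed, task):
    folds = kfold_split(len(y), k, seed, y)
    classes = sorted(np.unique(y).tolist())
    reports = []
    for f, (train, test) in enumerate(folds):
        t0 = time.perf_counter()
        model = init_model(X.shape[1], len(classes), cfg)
        fit(model, X[train], y[train])
        scores = predict_scores(model, X[test])
        y_pred = predict(model, X[test])
        rep = _macro_multiclass_metrics(y[test], y_pred, scores, model.classes)
        rep.task, rep.fold = task, f
        rep.wall_time_s = time.perf_counter() - t0
        reports.append(rep)
    reports.append(_mean_report(reports, task))
    return reports


def _augmented_fit_arrays(records, images, train_idx, extractor, enhance, seed):
    """Augment the training rows only (4 variants each), then extract.

    Augmenting before the fold split would leak variants of one image
    across folds, so augmentation happens inside each fold.
    """
    rng = np.random.default_rng(seed)
    aug_images, aug_records = [], []
    for i in train_idx:
        for variant in core_io.augment(images[i], rng):
            aug_images.append(variant)
            aug_records.append(records[i])
    X = extract_matrix(aug_records, extractor, enhance=enhance, images=aug_images)
    y = np.array([r.stage.value for r in aug_records], dtype=object)
    return X, y


def _reports_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    # wall times live in a separate timing file: metric CSVs are part of the
    # byte-identical determinism contract, timings are hardware-dependent
    return pd.DataFrame(
        {
            "task": [r.task for r in reports],
            "fold": ["mean" if r.fold is None else r.fold for r in reports],
            "accuracy": [r.accuracy for r in reports],
            "precision": [r.precision for r in reports],
            "recall": [r.recall for r in reports],
            "f1": [r.f1 for r in reports],
            "auc": [r.auc for r in reports],
        }
    )


def _timing_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "task": [r.task for r in reports],
            "fold": ["mean" if r.fold is None else r.fold for r in reports],
            "time_s": [r.wall_time_s for r in reports],
        }
    )


def _task_arrays(records, task: str):
    if task == "multiclass":
        y = np.array([r.stage.value for r in records], dtype=object)
        return list(records), y, None
    if not task.startswith("normal_vs_"):
        raise ValueError(f"unknown task {task!r}; expected normal_vs_<stage> or multiclass")
    stage = StrokeStage.parse(task.removeprefix("normal_vs_"))
    kept, y = binary_task(records, stage)
    return kept, y, stage.value


def run_experiment(cfg: RunConfig) -> dict[str, Path]:
    """Run the full protocol and write report CSVs into ``cfg.out_dir``.

    Pipeline: manifest -> task filter -> (optional SPEM) -> feature
    extraction -> edRVFL k-fold CV; per-fold rows plus a mean row go to
    ``metrics_<mode>.csv``. With ``spem="both"`` the run is executed on raw
    and on enhanced images and a paired comparison table
    (``comparison.csv``) is written as well. Metric CSVs are deterministic
    given the seed — reruns are byte-identical; hardware-dependent wall
    times go to separate ``timing_<mode>.csv`` files and the comparison
    table.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = core_io.read_manifest(Path(cfg.manifest))
    records, y, positive = _task_arrays(records, cfg.task)
    extractor = cfg.extractor or BlockStatExtractor()
    images = [core_io.load_image(r.image_path) for r in records]

    modes: list[tuple[str, SPEMConfig | None]]
    if cfg.spem == "both":
        modes = [("raw", None), ("enhanced", SPEMConfig())]
    elif isinstance(cfg.spem, SPEMConfig):
        modes = [("enhanced", cfg.spem)]
    else:
        modes = [("raw", None)]

    written: dict[str, Path] = {}
    summary_rows = []
    for mode, enhance in modes:
        t0 = time.perf_counter()
        if cfg.augment:
            reports = _cv_with_fold_augmentation(records, images, y, cfg, extractor, enhance, positive)
        else:
            X = extract_matrix(records, extractor, enhance=enhance, images=images)
            if cfg.task == "multiclass":
                reports = _cross_validate_multiclass(X, y, cfg.edrvfl, cfg.cv_folds, cfg.seed, cfg.task)
            else:
                reports = cross_validate(X, y, cfg.edrvfl, cfg.cv_folds, cfg.seed, positive, cfg.task)
        wall = time.perf_counter() - t0
        frame = _reports_frame(reports)
        path = out_dir / f"metrics_{mode}.csv"
        frame.to_csv(path, index=False, float_format=_CSV_FLOAT)
        timing_path = out_dir / f"timing_{mode}.csv"
        _timing_frame(reports).to_csv(timing_path, index=False, float_format=_CSV_FLOAT)
        written[mode] = path
        written[f"timing_{mode}"] = timing_path
        mean = reports[-1]
        summary_rows.append(
            {
                "mode": mode,
                "task": cfg.task,
                "accuracy": mean.accuracy,
                "precision": mean.precision,
                "recall": mean.recall,
                "f1": mean.f1,
                "auc": mean.auc,
                "wall_time_s": wall,
            }
        )
        logger.info("%s/%s: mean accuracy %.4f (%.1fs)", cfg.task, mode, mean.accuracy, wall)

    if len(modes) > 1:
        comp = out_dir / "comparison.csv"
        pd.DataFrame(summary_rows).to_csv(comp, index=False, float_format=_CSV_FLOAT)
        written["comparison"] = comp
    return written


def _cv_with_fold_augmentation(records, images, y, cfg, extractor, enhance, positive):
    """CV where each fold's training images are augmented ×4 in-fold."""
    folds = kfold_split(len(y), cfg.cv_folds, cfg.seed, y)
    reports = []
    classes = sorted(np.unique(y).tolist())
    for f, (train, test) in enumerate(folds):
        t0 = time.perf_counter()
        X_train, y_train = _augmented_fit_arrays(
            records, images, train, extractor, enhance, seed=cfg.seed * 1009 + f
        )
        X_test = extract_matrix(
            [records[i] for i in test], extractor, enhance=enhance, images=[images[i] for i in test]
        )
        model = init_model(X_train.shape[1], len(classes), cfg.edrvfl)
        fit(model, X_train, y_train)
        scores = predict_scores(model, X_test)
        y_pred = predict(model, X_test)
        if cfg.task == "multiclass":
            rep = _macro_multiclass_metrics(y[test], y_pred, scores, model.classes)
        else:
            rep = compute_metrics(y[test], y_pred, _positive_scores(model, scores, positive), positive)
        rep.task, rep.fold = cfg.task, f
        rep.wall_time_s = time.perf_counter() - t0
        reports.append(rep)
    reports.append(_mean_report(reports, cfg.task))
    return reports
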