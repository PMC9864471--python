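"""Experimental protocols and classification metrics.

Two evaluation settings are implemented:

* **Speaker-dependent** (Setting 1): frames of every class are split
  80/10/10 into train/test/validation at the frame level, so frames of
  the same speaker can appear on both sides.  This estimates performance
  on *already seen* speakers (e.g. recurring patients).
* **Speaker-independent** (Setting 2): subjects of every class are
  partitioned into k folds and cross-validated so that train and test
  speakers never overlap.  This estimates performance on *new*
  speakers and is the clinically realistic protocol.

Metrics are per-class one-vs-rest precision, recall and F1 computed
from a K x K confusion matrix (rows = true class, columns = predicted),
reported in percent:

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import gcnn as _gcnn
from .gcnn import GCNNConfig, GCNNParams, TrainHistory, init_model, predict_proba
from .preprocess import (
    FeatureMatrix,
    FrameDataset,
    ScalingParams,
    apply_robust_scaler,
    filter_low_variance_features,
    fit_robust_scaler,
)
from .simgraph import NeighborhoodGraph, select_neighborhoods, similarity_matrix

__all__ = [
    "SPEAKER_DEPENDENT",
    "SPEAKER_INDEPENDENT",
    "SplitSpec",
    "ConfusionMatrix",
    "MetricsReport",
    "FoldResults",
    "ExperimentResult",
    "split_speaker_dependent",
    "split_speaker_independent",
    "confusion_matrix",
    "metrics_from_confusion",
    "mean_report",
    "fit_frontend",
    "run_speaker_dependent",
    "cross_validate",
]

SPEAKER_DEPENDENT = "speaker_dependent"
SPEAKER_INDEPENDENT = "speaker_independent"


@dataclass
class SplitSpec:
    """How to partition a dataset for one of the two settings."""

    mode: str = SPEAKER_DEPENDENT
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train, test, val
    k_folds: int = 5
    seed: int = 0
    val_subject_fraction: float = 0.125  # share of training subjects held out for validation

    def __post_init__(self) -> None:
        if self.mode not in (SPEAKER_DEPENDENT, SPEAKER_INDEPENDENT):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == SPEAKER_DEPENDENT:
            if any(r <= 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
                raise ValueError("ratios must be positive and sum to 1")
        elif self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.class_labels)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy = trace / total (equals micro-averaged recall)."""
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_labels, columns=self.class_labels)


@dataclass
class MetricsReport:
    """Per-class one-vs-rest precision/recall/F1 in percent, plus accuracy."""

    class_labels: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    support: np.ndarray

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            },
            index=self.class_labels,
        )
        if decimals is not None:
            df[["precision", "recall", "f1"]] = df[["precision", "recall", "f1"]].round(decimals)
        return df


def confusion_matrix(
    true_labels: Sequence[int],
    pred_labels: Sequence[int],
    n_classes: int,
    class_labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally a K x K confusion matrix from parallel label arrays."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays must have equal length")
    for name, arr in (("true", t), ("predicted", p)):
        if len(arr) and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} label out of range 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    labels = list(class_labels) if class_labels else [f"class {i}" for i in range(n_classes)]
    return ConfusionMatrix(counts, labels)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision, recall and F1 (percent) from a confusion matrix.

    Each class is scored one-vs-rest: TP is the diagonal entry, FP the
    rest of its column, FN the rest of its row.  A metric whose
    denominator is zero is reported as 0 (with a warning), which is how
    a class that is never predicted shows up.
    """
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if np.any((tp + fp == 0) | (tp + fn == 0)):
        degenerate = [
            cm.class_labels[i]
            for i in range(len(tp))
            if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0
        ]
        warnings.warn(
            f"degenerate classes (zero denominator), metrics reported as 0: {degenerate}",
            stacklevel=2,
        )
    return MetricsReport(
        list(cm.class_labels),
        precision * 100.0,
        recall * 100.0,
        f1 * 100.0,
        cm.accuracy * 100.0,
        cm.counts.sum(axis=1),
    )


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of per-class metrics across folds."""
    if not reports:
        raise ValueError("no reports to average")
    labels = reports[0].class_labels
    return MetricsReport(
        list(labels),
        np.mean([r.precision for r in reports], axis=0),
        np.mean([r.recall for r in reports], axis=0),
        np.mean([r.f1 for r in reports], axis=0),
        float(np.mean([r.accuracy for r in reports])),
        np.sum([r.support for r in reports], axis=0),
    )


def split_speaker_dependent(
    ds: FrameDataset, spec: SplitSpec
) -> tuple[FrameDataset, FrameDataset, FrameDataset]:
    """Frame-level stratified split into (train, test, val) by class.

    Frames of each class are shuffled with the spec seed and divided by
    the given ratios; the same subject may appear in several partitions
    (that is the point of the speaker-dependent protocol).
    """
    rng = np.random.default_rng(spec.seed)
    r_tr, r_te, _ = spec.ratios
    tr_idx, te_idx, va_idx = [], [], []
    for c in range(ds.n_classes):
        idx = np.flatnonzero(ds.y == c)
        if len(idx) == 0:
            raise ValueError(f"class {ds.class_labels[c]!r} has no frames")
        if len(idx) < 10:
            raise ValueError(
                f"class {ds.class_labels[c]!r} has only {len(idx)} frames (< 10)"
            )
        idx = rng.permutation(idx)
        n_tr = int(np.floor(r_tr * len(idx)))
        n_te = int(np.floor(r_te * len(idx)))
        tr_idx.append(idx[:n_tr])
        te_idx.append(idx[n_tr : n_tr + n_te])
        va_idx.append(idx[n_tr + n_te :])
    return (
        ds.subset(np.concatenate(tr_idx)),
        ds.subset(np.concatenate(te_idx)),
        ds.subset(np.concatenate(va_idx)),
    )


def split_speaker_independent(ds: FrameDataset, spec: SplitSpec) -> list[list[str]]:
    """Partition subjects of each class across k folds (sizes differ <= 1).

    Every subject lands in exactly one fold; fold i's test frames come
    only from fold-i subjects, so train and test speakers are completely
    separated.
    """
    rng = np.random.default_rng(spec.seed)
    folds: list[list[str]] = [[] for _ in range(spec.k_folds)]
    for c in range(ds.n_classes):
        subs = ds.subjects_of_class(c)
        if len(subs) < spec.k_folds:
            raise ValueError(
                f"class {ds.class_labels[c]!r} has {len(subs)} subjects, "
                f"fewer than k_folds={spec.k_folds}"
            )
        subs = [subs[i] for i in rng.permutation(len(subs))]
        for i, s in enumerate(subs):
            folds[i % spec.k_folds].append(s)
    return folds


def fit_frontend(
    train_X: np.ndarray,
    feature_names: Sequence[str],
    m: int = 9,
    include_self: bool = True,
    variance_tol: float = 1e-10,
) -> tuple[list[str], ScalingParams, NeighborhoodGraph]:
    """Fit the data-dependent stages on training frames only.

    Variance filter, robust scaler and similarity graph are all
    estimated from the training split and frozen; test frames are only
    ever transformed, never used for fitting.
    """
    fm = FeatureMatrix(train_X, list(feature_names), np.array(["_"] * len(train_X), dtype=object))
    kept, _ = filter_low_variance_features(fm, variance_tol)
    scaler = fit_robust_scaler(kept)
    scaled = apply_robust_scaler(kept, scaler)
    graph = select_neighborhoods(similarity_matrix(scaled), m=m, include_self=include_self)
    return list(kept.feature_names), scaler, graph


def _transform(X: np.ndarray, names: Sequence[str], kept: Sequence[str], scaler: ScalingParams) -> np.ndarray:
    cols = [list(names).index(n) for n in kept]
    return (X[:, cols] - scaler.median) / scaler.iqr


@dataclass
class ExperimentResult:
    """One trained model evaluated on one held-out test set."""

    report: MetricsReport
    confusion: ConfusionMatrix
    history: TrainHistory
    params: GCNNParams
    graph: NeighborhoodGraph
    kept_features: list[str]
    scaler: ScalingParams

    @property
    def test_accuracy(self) -> float:
        return self.confusion.accuracy


@dataclass
class FoldResults:
    """Per-fold reports of a cross-validation plus their mean."""

    fold_reports: list[MetricsReport]
    fold_confusions: list[ConfusionMatrix]
    mean: MetricsReport
    fold_subjects: list[list[str]]


def _train_eval(
    ds: FrameDataset,
    train_ds: FrameDataset,
    val_ds: FrameDataset,
    test_ds: FrameDataset,
    cfg: GCNNConfig,
    m: int | None,
    include_self: bool,
    variance_tol: float,
) -> ExperimentResult:
    # the graph's receptive-field width and the kernel width must agree;
    # an explicit m overrides the model config
    if m is not None and m != cfg.m:
        import dataclasses

        cfg = dataclasses.replace(cfg, m=m)
    m = cfg.m
    kept, scaler, graph = fit_frontend(
        train_ds.X, ds.feature_names, m=m, include_self=include_self, variance_tol=variance_tol
    )
    Xtr = _transform(train_ds.X, ds.feature_names, kept, scaler)
    Xva = _transform(val_ds.X, ds.feature_names, kept, scaler)
    Xte = _transform(test_ds.X, ds.feature_names, kept, scaler)
    params = init_model(cfg, graph)
    params, history = _gcnn.train(params, cfg, graph, (Xtr, train_ds.y), (Xva, val_ds.y))
    preds = predict_proba(params, cfg, graph, Xte).argmax(axis=1)
    cm = confusion_matrix(test_ds.y, preds, ds.n_classes, ds.class_labels)
    return ExperimentResult(
        metrics_from_confusion(cm), cm, history, params, graph, kept, scaler
    )


def run_speaker_dependent(
    ds: FrameDataset,
    cfg: GCNNConfig,
    spec: SplitSpec | None = None,
    m: int | None = None,
    include_self: bool = True,
    variance_tol: float = 1e-10,
) -> ExperimentResult:
    """Setting 1: stratified frame-level 80/10/10 split, train, evaluate."""
    spec = spec or SplitSpec(mode=SPEAKER_DEPENDENT)
    if spec.mode != SPEAKER_DEPENDENT:
        raise ValueError("spec.mode must be speaker_dependent")
    train_ds, test_ds, val_ds = split_speaker_dependent(ds, spec)
    return _train_eval(ds, train_ds, val_ds, test_ds, cfg, m, include_self, variance_tol)


def cross_validate(
    ds: FrameDataset,
    cfg: GCNNConfig,
    spec: SplitSpec | None = None,
    m: int | None = None,
    include_self: bool = True,
    variance_tol: float = 1e-10,
) -> FoldResults:
    """Setting 2: subject-grouped k-fold cross-validation.

    Per fold: the fold's subjects are the test set; a subject-grouped
    validation set (``spec.val_subject_fraction`` of training subjects,
    at least one) is carved from the remaining subjects for early
    stopping; scaler and similarity graph are re-fit on the fold's
    training frames; metrics are averaged across folds.
    """
    spec = spec or SplitSpec(mode=SPEAKER_INDEPENDENT)
    if spec.mode != SPEAKER_INDEPENDENT:
        raise ValueError("spec.mode must be speaker_independent")
    folds = split_speaker_independent(ds, spec)
    all_subjects = set(ds.subject_ids)
    reports, confusions = [], []
    for i, test_subjects in enumerate(folds):
        test_set = set(test_subjects)
        train_subjects = sorted(all_subjects - test_set)
        assert not test_set & set(train_subjects), "fold leakage: subject in both sides"
        rng = np.random.default_rng(spec.seed + 1000 * (i + 1))
        n_val = max(1, int(round(spec.val_subject_fraction * len(train_subjects))))
        val_subjects = set(
            np.array(train_subjects, dtype=object)[
                rng.permutation(len(train_subjects))[:n_val]
            ]
        )
        fit_subjects = set(train_subjects) - val_subjects
        is_test = np.isin(ds.subject_ids.astype(str), list(test_set))
        is_val = np.isin(ds.subject_ids.astype(str), [str(s) for s in val_subjects])
        is_fit = np.isin(ds.subject_ids.astype(str), [str(s) for s in fit_subjects])
        res = _train_eval(
            ds,
            ds.subset(np.flatnonzero(is_fit)),
            ds.subset(np.flatnonzero(is_val)),
            ds.subset(np.flatnonzero(is_test)),
            cfg,
            m,
            include_self,
            variance_tol,
        )
        reports.append(res.report)
        confusions.append(res.confusion)
    return FoldResults(reports, confusions, mean_report(reports), folds)
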