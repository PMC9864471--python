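"""Ingestion and preprocessing of frame-level voice-feature tables.

The pipeline starts from per-subject CSV tables of frame-level audio
features (one row per 10 ms voiced frame, one column per feature, e.g.
COVAREP-style vectors) plus a subject metadata table carrying PHQ-8
depression scores.  This module handles loading, exclusion of
near-constant features (whose Pearson correlations are ill-defined),
robust scaling to median 0 / interquartile range 1, mapping of PHQ-8
scores to severity classes, and assembly of a labeled frame-level
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "FeatureMatrix",
    "SubjectRecord",
    "SeverityScheme",
    "ScalingParams",
    "FrameDataset",
    "severity_scheme",
    "binary_scheme",
    "load_feature_table",
    "load_cohort_dir",
    "filter_low_variance_features",
    "fit_robust_scaler",
    "apply_robust_scaler",
    "assign_severity_class",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]

#: Sentinel class index for subjects excluded from the study
#: (PHQ-8 at or above the scheme's exclusion threshold).
EXCLUDED = -1


@dataclass
class FeatureMatrix:
    """Frames-by-features table with per-frame subject identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_frames, n_features)``; unitless
        feature values, all finite.
    feature_names
        Unique column names, one per feature.
    subject_ids
        Per-frame subject identifier, length ``n_frames``.
    frame_period
        Seconds between consecutive frames (default 10 ms).
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: np.ndarray
    frame_period: float = 0.010

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match n_features")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match n_frames")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {r}, column {self.feature_names[c]!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SubjectRecord:
    """Metadata for one subject: identifier, PHQ-8 total score, gender."""

    subject_id: str
    phq8: int
    gender: str | None = None
    severity_class: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= int(self.phq8) <= 24:
            raise ValueError(
                f"PHQ-8 score must be in 0..24, got {self.phq8} "
                f"for subject {self.subject_id!r}"
            )
        self.phq8 = int(self.phq8)


@dataclass
class SeverityScheme:
    """Mapping from PHQ-8 scores to ordinal severity classes.

    ``upper_bounds`` are inclusive upper cut points, one per class,
    partitioning ``0 .. exclusion_min - 1`` into contiguous non-empty
    ranges.  Scores at or above ``exclusion_min`` are excluded from the
    study entirely.
    """

    class_labels: list[str]
    upper_bounds: list[int]
    exclusion_min: int = 21

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.upper_bounds):
            raise ValueError("one upper bound required per class")
        bounds = list(self.upper_bounds)
        if any(b >= c for b, c in zip(bounds, bounds[1:])):
            raise ValueError("upper_bounds must be strictly increasing")
        if bounds[-1] != self.exclusion_min - 1:
            raise ValueError(
                "bounds must partition 0..exclusion_min-1 "
                f"(last bound {bounds[-1]} != {self.exclusion_min - 1})"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def score_range(self, class_index: int) -> tuple[int, int]:
        """Inclusive (low, high) PHQ-8 range of a class."""
        lo = 0 if class_index == 0 else self.upper_bounds[class_index - 1] + 1
        return lo, self.upper_bounds[class_index]


def severity_scheme() -> SeverityScheme:
    """Default four-stage scheme: 0-9 / 10-14 / 15-19 / 20, exclude >= 21."""
    return SeverityScheme(
        class_labels=["Nondepression", "First stage", "Intermediate stage", "Final stage"],
        upper_bounds=[9, 14, 19, 20],
        exclusion_min=21,
    )


def binary_scheme() -> SeverityScheme:
    """Diagnostic scheme: nondepression 0-9 vs depression 10-20, exclude >= 21."""
    return SeverityScheme(
        class_labels=["Nondepression", "Depression"],
        upper_bounds=[9, 20],
        exclusion_min=21,
    )


@dataclass
class ScalingParams:
    """Per-feature median and interquartile range fitted on training frames."""

    feature_names: list[str]
    median: np.ndarray
    iqr: np.ndarray

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=np.float64)
        self.iqr = np.asarray(self.iqr, dtype=np.float64)
        if not (len(self.feature_names) == len(self.median) == len(self.iqr)):
            raise ValueError("feature_names, median, iqr must have equal length")
        if np.any(self.iqr <= 0):
            bad = [n for n, q in zip(self.feature_names, self.iqr) if q <= 0]
            raise ValueError(f"non-positive IQR for features {bad}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "median": self.median.tolist(),
                    "iqr": self.iqr.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        d = json.loads(Path(path).read_text())
        return cls(d["feature_names"], np.array(d["median"]), np.array(d["iqr"]))


@dataclass
class FrameDataset:
    """Labeled frame-level dataset: scaled features, class labels, subjects."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    feature_names: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if not (self.X.shape[0] == len(self.y) == len(self.subject_ids)):
            raise ValueError("X, y, subject_ids must agree on n_frames")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "FrameDataset":
        return FrameDataset(
            self.X[idx], self.y[idx], self.subject_ids[idx],
            self.feature_names, self.class_labels,
        )

    def subjects_of_class(self, c: int) -> list[str]:
        return sorted(set(self.subject_ids[self.y == c]))


def load_feature_table(path: str | Path, subject_id: str) -> FeatureMatrix:
    """Read one subject's frame-level feature CSV.

    The CSV must have a header row of feature names and an all-numeric
    body; every row is tagged with ``subject_id`` and row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"no frames in {path} (header-only CSV)")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric or missing cell in {path}: "
                f"row {bad[0]}, column {col!r}"
            )
    values = df.to_numpy(dtype=np.float64)
    return FeatureMatrix(
        values=values,
        feature_names=[str(c) for c in df.columns],
        subject_ids=np.array([subject_id] * len(df), dtype=object),
    )


def load_cohort_dir(data_dir: str | Path) -> tuple[list[FeatureMatrix], list[SubjectRecord]]:
    """Load a cohort directory: ``subjects.csv`` + ``frames/<subject_id>.csv``."""
    data_dir = Path(data_dir)
    meta_path = data_dir / "subjects.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"subject metadata not found: {meta_path}")
    meta = pd.read_csv(meta_path, dtype={"subject_id": str})
    subjects, tables = [], []
    for _, row in meta.iterrows():
        gender = row.get("gender")
        if pd.isna(gender):
            gender = None
        rec = SubjectRecord(str(row["subject_id"]), int(row["phq8"]), gender)
        subjects.append(rec)
        tables.append(
            load_feature_table(data_dir / "frames" / f"{rec.subject_id}.csv", rec.subject_id)
        )
    return tables, subjects


def filter_low_variance_features(
    fm: FeatureMatrix, tol: float = 1e-10
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features whose sample variance is at or below ``tol``.

    Near-constant features make Pearson correlations ill-defined and
    must be removed before similarity graphs are built.  Survivors keep
    their column order.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    var = np.var(fm.values, axis=0, ddof=1) if fm.n_frames > 1 else np.zeros(fm.n_features)
    keep = var > tol
    if not keep.any():
        raise ValueError("all features excluded by the variance filter")
    excluded = [n for n, k in zip(fm.feature_names, keep) if not k]
    kept = FeatureMatrix(
        fm.values[:, keep],
        [n for n, k in zip(fm.feature_names, keep) if k],
        fm.subject_ids,
        fm.frame_period,
    )
    return kept, excluded


def fit_robust_scaler(fm: FeatureMatrix) -> ScalingParams:
    """Fit per-feature median and IQR (Q3 - Q1, linear interpolation).

    Fit on training frames only; apply to every split with
    :func:`apply_robust_scaler` so that test frames never leak into the
    normalization.
    """
    q1, med, q3 = np.percentile(fm.values, [25, 50, 75], axis=0)
    iqr = q3 - q1
    if np.any(iqr <= 0):
        bad = [n for n, q in zip(fm.feature_names, iqr) if q <= 0]
        raise ValueError(
            f"zero IQR for features {bad}; run filter_low_variance_features first"
        )
    return ScalingParams(list(fm.feature_names), med, iqr)


def apply_robust_scaler(fm: FeatureMatrix, sp: ScalingParams) -> FeatureMatrix:
    """Map every value to (value - median) / IQR using fitted parameters."""
    if list(fm.feature_names) != list(sp.feature_names):
        diff = set(fm.feature_names) ^ set(sp.feature_names)
        raise ValueError(
            f"feature names do not match scaler: differing features {sorted(diff) or 'order mismatch'}"
        )
    return FeatureMatrix(
        (fm.values - sp.median) / sp.iqr,
        fm.feature_names,
        fm.subject_ids,
        fm.frame_period,
    )


def assign_severity_class(phq8: int, scheme: SeverityScheme) -> int:
    """Map a PHQ-8 score to its class index, or ``EXCLUDED`` if at/above
    the scheme's exclusion threshold."""
    phq8 = int(phq8)
    if not 0 <= phq8 <= 24:
        raise ValueError(f"PHQ-8 score must be in 0..24, got {phq8}")
    if phq8 >= scheme.exclusion_min:
        return EXCLUDED
    for idx, ub in enumerate(scheme.upper_bounds):
        if phq8 <= ub:
            return idx
    raise AssertionError("unreachable: bounds partition the score range")


def build_dataset(
    tables: Sequence[FeatureMatrix],
    subjects: Sequence[SubjectRecord],
    scheme: SeverityScheme,
    exclude_subjects: Sequence[str] = (),
) -> FrameDataset:
    """Concatenate per-subject tables into one labeled frame dataset.

    Subjects whose PHQ-8 score falls at or above the exclusion threshold,
    and subjects listed in ``exclude_subjects`` (e.g. known mislabeled
    ids), are dropped along with all their frames.  Every table must have
    a matching subject record and vice versa.
    """
    by_id = {s.subject_id: s for s in subjects}
    table_ids = []
    for t in tables:
        ids = set(t.subject_ids)
        if len(ids) != 1:
            raise ValueError("each input table must belong to a single subject")
        table_ids.append(next(iter(ids)))
    orphan_tables = [i for i in table_ids if i not in by_id]
    if orphan_tables:
        raise ValueError(f"tables without subject records: {orphan_tables}")
    orphan_records = sorted(set(by_id) - set(table_ids))
    if orphan_records:
        raise ValueError(f"subject records without tables: {orphan_records}")

    names = tables[0].feature_names
    drop = set(exclude_subjects)
    parts_X, parts_y, parts_s = [], [], []
    for t, sid in zip(tables, table_ids):
        if list(t.feature_names) != list(names):
            raise ValueError(f"feature names of {sid} differ from first table")
        rec = by_id[sid]
        cls = assign_severity_class(rec.phq8, scheme)
        rec.severity_class = cls
        if cls == EXCLUDED or sid in drop:
            continue
        parts_X.append(t.values)
        parts_y.append(np.full(t.n_frames, cls, dtype=np.int64))
        parts_s.append(t.subject_ids)
    if not parts_X:
        raise ValueError("no subjects retained after exclusions")
    return FrameDataset(
        np.vstack(parts_X),
        np.concatenate(parts_y),
        np.concatenate(parts_s),
        list(names),
        list(scheme.class_labels),
    )


def save_dataset(ds: FrameDataset, path: str | Path) -> None:
    """Persist a labeled dataset to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ds.X)
        f.create_dataset("y", data=ds.y)
        str_dt = h5py.string_dtype()
        f.create_dataset(
            "subject_ids", data=[str(s) for s in ds.subject_ids], dtype=str_dt
        )
        f.create_dataset("feature_names", data=ds.feature_names, dtype=str_dt)
        f.create_dataset("class_labels", data=ds.class_labels, dtype=str_dt)


def load_dataset(path: str | Path) -> FrameDataset:
    with h5py.File(path, "r") as f:
        return FrameDataset(
            f["X"][()],
            f["y"][()],
            np.array([s.decode() for s in f["subject_ids"][()]], dtype=object),
            [s.decode() for s in f["feature_names"][()]],
            [s.decode() for s in f["class_labels"][()]],
        )
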