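"""Correlation-based similarity graphs over audio features.

The similarity between two features x and y is the absolute Pearson
correlation coefficient computed over the training frames:

    S(x, y) = | sum_i (x_i - x̄)(y_i - ȳ) |
              / sqrt( sum_i (x_i - x̄)^2 · sum_i (y_i - ȳ)^2 )

For each feature, the m most similar features form its "neighborhood";
the feature and its neighbors are the nodes of a star graph (neighbors
are not connected to each other).  These per-feature stars are the
receptive fields of the graph convolution.

A note on ``include_self``: the convolution kernels span ``m`` taps.
With ``include_self=True`` (default) each feature's list is the feature
itself (similarity 1) followed by its top ``m - 1`` neighbors, so the
receptive-field width equals ``m``.  With ``include_self=False`` the
list holds the top ``m`` *other* features and the receptive field is
the center plus those neighbors (width ``m + 1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import FeatureMatrix

__all__ = [
    "SimilarityMatrix",
    "NeighborhoodGraph",
    "similarity",
    "similarity_matrix",
    "select_neighborhoods",
    "neighborhood_selection_counts",
    "graph_to_json",
    "graph_from_json",
    "export_similarity_heatmap",
    "export_selection_counts",
]


@dataclass
class SimilarityMatrix:
    """Absolute-Pearson similarity between every pair of features."""

    values: np.ndarray
    feature_names: list[str]
    n_fit_frames: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.feature_names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match feature_names")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class NeighborhoodGraph:
    """Per-feature ordered neighbor lists (one star graph per feature).

    ``neighbor_indices[f]`` holds exactly ``m`` feature indices sorted by
    non-increasing similarity to feature ``f`` (ties broken by ascending
    index); ``neighbor_similarities`` holds the matching similarities.
    """

    m: int
    include_self: bool
    neighbor_indices: np.ndarray
    neighbor_similarities: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.neighbor_indices = np.asarray(self.neighbor_indices, dtype=np.int64)
        self.neighbor_similarities = np.asarray(self.neighbor_similarities, dtype=np.float64)
        F = len(self.feature_names)
        if self.neighbor_indices.shape != (F, self.m):
            raise ValueError(f"neighbor_indices must be (n_features, m)={F, self.m}")
        if self.neighbor_similarities.shape != (F, self.m):
            raise ValueError("neighbor_similarities must match neighbor_indices")
        if self.neighbor_indices.min() < 0 or self.neighbor_indices.max() >= F:
            raise ValueError("neighbor index out of range")
        for f in range(F):
            row = self.neighbor_indices[f]
            if len(set(row.tolist())) != self.m:
                raise ValueError(f"duplicate neighbor for feature {f}")
            sims = self.neighbor_similarities[f]
            if np.any(np.diff(sims) > 1e-12):
                raise ValueError(f"similarities not non-increasing for feature {f}")
            if not self.include_self and f in row:
                raise ValueError(f"feature {f} appears in its own neighbor list")
            if self.include_self and row[0] != f:
                raise ValueError(f"center must be first in its own list (feature {f})")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def width(self) -> int:
        """Receptive-field width seen by the convolution kernels."""
        return self.m if self.include_self else self.m + 1

    @property
    def receptive_fields(self) -> np.ndarray:
        """(n_features, width) index array: center first, then neighbors
        in descending similarity."""
        if self.include_self:
            return self.neighbor_indices
        centers = np.arange(self.n_features, dtype=np.int64)[:, None]
        return np.hstack([centers, self.neighbor_indices])


def similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation between two feature columns."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError(
            "zero-variance input; filter near-constant features before "
            "computing similarities"
        )
    return float(min(abs((xc * yc).sum() / (sx * sy)), 1.0))


def similarity_matrix(fm: FeatureMatrix) -> SimilarityMatrix:
    """All-pairs absolute Pearson similarity over the given (training) frames."""
    var = fm.values.var(axis=0)
    if np.any(var == 0):
        bad = [n for n, v in zip(fm.feature_names, var) if v == 0]
        raise ValueError(f"zero-variance features {bad}; filter them first")
    r = np.corrcoef(fm.values, rowvar=False)
    if not np.all(np.isfinite(r)):
        i, j = np.argwhere(~np.isfinite(r))[0]
        raise ValueError(
            f"non-finite similarity between {fm.feature_names[i]!r} "
            f"and {fm.feature_names[j]!r}"
        )
    s = np.abs(r)
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, list(fm.feature_names), fm.n_frames)


def select_neighborhoods(
    sm: SimilarityMatrix, m: int = 9, include_self: bool = True
) -> NeighborhoodGraph:
    """Pick each feature's top-``m`` neighborhood by descending similarity.

    Ties are broken by ascending feature index, making the graph
    deterministic.  See the module docstring for the ``include_self``
    convention; the neighbor relation is not symmetric in general.
    """
    F = sm.n_features
    max_m = F if include_self else F - 1
    if not 1 <= m <= max_m:
        raise ValueError(f"m must be in 1..{max_m}, got {m}")
    n_others = m - 1 if include_self else m
    indices = np.empty((F, m), dtype=np.int64)
    sims = np.empty((F, m))
    for f in range(F):
        row = sm.values[f].copy()
        row[f] = -np.inf  # self handled explicitly
        # descending similarity, ties by ascending index
        order = np.lexsort((np.arange(F), -row))
        chosen = order[:n_others]
        if include_self:
            indices[f] = np.concatenate([[f], chosen])
            sims[f] = np.concatenate([[1.0], sm.values[f, chosen]])
        else:
            indices[f] = chosen
            sims[f] = sm.values[f, chosen]
    return NeighborhoodGraph(m, include_self, indices, sims, list(sm.feature_names))


def neighborhood_selection_counts(g: NeighborhoodGraph) -> np.ndarray:
    """How often each feature appears in *other* features' neighbor lists.

    For an ``include_self=False`` graph the counts sum to
    ``n_features * m``; with ``include_self=True`` the center entries are
    skipped, so they sum to ``n_features * (m - 1)``.
    """
    counts = np.zeros(g.n_features, dtype=np.int64)
    for f in range(g.n_features):
        row = g.neighbor_indices[f, 1:] if g.include_self else g.neighbor_indices[f]
        np.add.at(counts, row, 1)
    return counts


def graph_to_json(g: NeighborhoodGraph, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "m": g.m,
                "include_self": g.include_self,
                "feature_names": g.feature_names,
                "neighbor_indices": g.neighbor_indices.tolist(),
                "neighbor_similarities": g.neighbor_similarities.tolist(),
            },
            indent=2,
        )
    )


def graph_from_json(path: str | Path) -> NeighborhoodGraph:
    d = json.loads(Path(path).read_text())
    return NeighborhoodGraph(
        d["m"],
        d["include_self"],
        np.array(d["neighbor_indices"]),
        np.array(d["neighbor_similarities"]),
        d["feature_names"],
    )


def export_similarity_heatmap(
    sm: SimilarityMatrix, csv_path: str | Path, png_path: str | Path | None = None
) -> None:
    """Write the similarity matrix as CSV and, optionally, a heat-map PNG."""
    import pandas as pd

    pd.DataFrame(sm.values, index=sm.feature_names, columns=sm.feature_names).to_csv(csv_path)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 7))
        im = ax.imshow(sm.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_title("Absolute Pearson similarity between audio features")
        fig.colorbar(im, ax=ax, label="|r|")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def export_selection_counts(
    g: NeighborhoodGraph, csv_path: str | Path, png_path: str | Path | None = None
) -> None:
    """Write per-feature neighborhood-selection counts as CSV / bar chart."""
    import pandas as pd

    counts = neighborhood_selection_counts(g)
    pd.DataFrame({"feature": g.feature_names, "times_selected": counts}).to_csv(
        csv_path, index=False
    )
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4))
        ax.bar(np.arange(g.n_features), counts)
        ax.set_xlabel("feature index")
        ax.set_ylabel("times selected as neighbor")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
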