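"""Between-group analysis (BGA) of expression data sets.

BGA is a supervised ordination: principal axes are computed on the matrix
of group centroids (weighted by group size) rather than on individual
samples, and the samples are then projected onto those axes. With g
groups at most g - 1 axes carry between-group variance. A silhouette
score on the projected samples quantifies how cleanly the groups
segregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score


@dataclass
class BGAResult:
    """Axes, centroid coordinates and sample projections of one BGA."""

    axes: np.ndarray  # probes x n_axes loadings
    group_centroids: pd.DataFrame  # groups x n_axes
    sample_scores: pd.DataFrame  # samples x n_axes, plus 'group' column
    inertia_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]


def between_group_analysis(expression: pd.DataFrame, labels: list) -> BGAResult:
    """Ordinate data sets by their group structure.

    ``expression`` is probes x data sets; ``labels`` assigns a group to
    each column. Rows are centered, group centroids are computed and a
    size-weighted PCA of the centroid matrix gives up to (g - 1) axes;
    individual data sets are projected onto them.
    """
    labels = list(labels)
    if expression.shape[1] != len(labels):
        raise ValueError("one label per expression column is required")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = {g: labels.count(g) for g in groups}
    singletons = [g for g, c in counts.items() if c < 2]
    if singletons:
        raise ValueError(f"groups with a single member cannot be ordinated: {singletons}")

    X = expression.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)  # center per probe

    label_arr = np.asarray(labels)
    centroids = np.column_stack([X[:, label_arr == g].mean(axis=1) for g in groups])
    weights = np.array([counts[g] for g in groups], dtype=float)
    weights /= weights.sum()

    # weighted PCA of centroids: SVD of centroids scaled by sqrt(weights)
    C = centroids * np.sqrt(weights)
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    n_axes = min(len(groups) - 1, int((s > 1e-12 * max(s[0], 1e-300)).sum()))
    n_axes = max(n_axes, 1)
    axes = U[:, :n_axes]
    inertia = s**2
    total = inertia.sum()
    explained = inertia[:n_axes] / total if total > 0 else np.zeros(n_axes)

    axis_names = [f"axis{i + 1}" for i in range(n_axes)]
    centroid_scores = pd.DataFrame(centroids.T @ axes, index=groups, columns=axis_names)
    scores = pd.DataFrame(X.T @ axes, index=expression.columns, columns=axis_names)
    scores["group"] = labels
    return BGAResult(
        axes=axes,
        group_centroids=centroid_scores,
        sample_scores=scores,
        inertia_explained=explained,
    )


def separation_score(result: BGAResult) -> float:
    """Mean silhouette of the projected data sets under their group labels.

    Ranges over [-1, 1]: ~1 for cleanly segregated groups, ~0 for
    label-free structure, negative when groups interpenetrate. Computed in
    whatever axes the BGA retained (a single axis is fine).
    """
    coords = result.sample_scores.drop(columns="group").to_numpy(dtype=float)
    labels = result.sample_scores["group"].to_numpy()
    if len(set(labels.tolist())) < 2:
        raise ValueError("separation needs at least two groups")
    if np.allclose(coords.var(axis=0), 0.0):
        return 0.0  # degenerate collapse: no structure to separate
    return float(silhouette_score(coords, labels))
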