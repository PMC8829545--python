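"""Cluster-resolution selection by subject-wise cross-validated silhouettes.

The procedure: cluster all cells at each resolution of a grid; for each
resolution, hold out one subject at a time, train a random-forest
classifier on the clustering channels of the remaining subjects (labels
= cluster ids), transfer labels to the held-out subject's cells, and
compute their silhouette values under the predicted labels. Held-out
silhouettes are pooled across the folds, averaged within each predicted
cluster, and the unweighted mean over clusters is the resolution's
score. The chosen resolution is the elbow of the score-vs-resolution
curve (most negative discrete second difference), falling back to the
maximum score when the curve has no concave corner.

Two identical partitions found at different resolutions necessarily get
the same score, so scores are memoized per unique partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_samples

from .clustering import (
    DEFAULT_K,
    DEFAULT_MIN_CELLS,
    DEFAULT_PRUNE,
    UNASSIGNED,
    ClusterLabels,
    SNNGraph,
    cluster_graph,
    filter_clusters,
    knn_neighbors,
    snn_jaccard,
)
from .events import EventTable
from .io import PanelConfig

__all__ = [
    "FoldResult",
    "ResolutionScan",
    "silhouette_per_cell",
    "cv_fold",
    "cv_silhouette_score",
    "scan_resolutions",
    "select_elbow",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.linspace(0.01, 0.2, 20))
DEFAULT_SILHOUETTE_CAP = 5000
DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt"}


def silhouette_per_cell(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cell silhouette ``(b - a) / max(a, b)``, Euclidean.

    ``a`` is the mean distance to same-cluster cells (self excluded),
    ``b`` the smallest mean distance to another cluster. Cells in
    singleton clusters score 0. At least two clusters are required.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return silhouette_samples(points, labels, metric="euclidean")


@dataclass
class FoldResult:
    """Held-out predictions and silhouettes for one cross-validation fold."""

    held_out_subject: object
    cell_index: np.ndarray  # global indices of the scored held-out cells
    predicted: np.ndarray  # predicted cluster id per scored cell
    silhouette: np.ndarray  # in [-1, 1]

    def __post_init__(self) -> None:
        if len(self.silhouette) and (
            self.silhouette.min() < -1 - 1e-12 or self.silhouette.max() > 1 + 1e-12
        ):
            raise ValueError("silhouette values must lie in [-1, 1]")


class FoldSkipped(RuntimeError):
    """Raised when a fold cannot be scored (degenerate training labels)."""


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Row order independent of input permutation (lexicographic by features)."""
    return np.lexsort(X.T[::-1])


def _make_classifier(seed: int, classifier_params: dict | None) -> RandomForestClassifier:
    params = dict(DEFAULT_RF_PARAMS)
    if classifier_params:
        params.update(classifier_params)
    params.setdefault("random_state", seed)
    params.setdefault("n_jobs", 1)
    return RandomForestClassifier(**params)


def cv_fold(
    table: EventTable,
    labels: ClusterLabels,
    held_out,
    panel: PanelConfig,
    seed: int = 0,
    classifier_params: dict | None = None,
    silhouette_cap: int = DEFAULT_SILHOUETTE_CAP,
    train_cap: int | None = None,
) -> FoldResult:
    """One leave-one-subject-out fold.

    Trains on all assigned cells of the other subjects, predicts cluster
    ids for the held-out subject's cells, and scores their silhouettes
    under the predicted labels (uniform seeded subsample above
    ``silhouette_cap`` cells). Training rows are put in a canonical
    order first so the fold is invariant to cell order.
    """
    X = panel.clustering_matrix(table)
    held_mask = table.subject_id == held_out
    if not held_mask.any():
        raise ValueError(f"subject {held_out!r} not present")
    train_mask = ~held_mask & (labels.labels != UNASSIGNED)
    y_train = labels.labels[train_mask]
    if len(np.unique(y_train)) < 2:
        raise FoldSkipped(
            f"fold {held_out!r}: training labels cover fewer than 2 clusters"
        )
    X_train = X[train_mask]
    order = _canonical_order(X_train)
    X_train, y_train = X_train[order], y_train[order]
    rng = np.random.default_rng(seed)
    if train_cap is not None and len(y_train) > train_cap:
        pick = np.sort(rng.choice(len(y_train), size=train_cap, replace=False))
        X_train, y_train = X_train[pick], y_train[pick]

    clf = _make_classifier(seed, classifier_params)
    clf.fit(X_train, y_train)

    held_idx = np.flatnonzero(held_mask)
    if len(held_idx) > silhouette_cap:
        held_idx = np.sort(rng.choice(held_idx, size=silhouette_cap, replace=False))
    predicted = clf.predict(X[held_idx])
    if len(np.unique(predicted)) < 2:
        raise FoldSkipped(
            f"fold {held_out!r}: all held-out cells predicted into one cluster"
        )
    sil = silhouette_per_cell(X[held_idx], predicted)
    return FoldResult(
        held_out_subject=held_out,
        cell_index=held_idx,
        predicted=predicted,
        silhouette=sil,
    )


def cv_score_for_labels(
    table: EventTable,
    labels: ClusterLabels,
    panel: PanelConfig,
    seed: int = 0,
    classifier_params: dict | None = None,
    silhouette_cap: int = DEFAULT_SILHOUETTE_CAP,
    train_cap: int | None = None,
) -> tuple[float, dict[int, float], list[FoldResult]]:
    """Cross-validated score of one fixed partition.

    Runs one fold per subject, pools held-out silhouettes, averages them
    within each predicted cluster, then takes the unweighted mean over
    clusters (two-level average). Returns ``nan`` if every fold was
    skipped. Order of subjects does not affect the result.
    """
    subjects = table.subjects
    if len(subjects) < 3:
        raise ValueError("cross-validation needs at least 3 subjects")
    folds: list[FoldResult] = []
    for s in subjects:
        try:
            folds.append(
                cv_fold(table, labels, s, panel, seed=seed,
                        classifier_params=classifier_params,
                        silhouette_cap=silhouette_cap, train_cap=train_cap)
            )
        except FoldSkipped as e:
            logger.warning(str(e))
    if not folds:
        return float("nan"), {}, []
    pooled_pred = np.concatenate([f.predicted for f in folds])
    pooled_sil = np.concatenate([f.silhouette for f in folds])
    per_cluster = {
        int(c): float(pooled_sil[pooled_pred == c].mean())
        for c in np.unique(pooled_pred)
    }
    score = float(np.mean(list(per_cluster.values())))
    return score, per_cluster, folds


def cv_silhouette_score(
    table: EventTable,
    resolution: float,
    panel: PanelConfig,
    k: int = DEFAULT_K,
    seed: int = 0,
    prune_threshold: float = DEFAULT_PRUNE,
    min_cells: int = DEFAULT_MIN_CELLS,
    classifier_params: dict | None = None,
    silhouette_cap: int = DEFAULT_SILHOUETTE_CAP,
    train_cap: int | None = None,
    graph: SNNGraph | None = None,
) -> tuple[float, dict[int, float]]:
    """Cluster at one resolution and cross-validate the partition."""
    if graph is None:
        graph = snn_jaccard(knn_neighbors(table, panel, k), prune_threshold)
    labels = filter_clusters(cluster_graph(graph, resolution, seed), min_cells)
    score, per_cluster, _ = cv_score_for_labels(
        table, labels, panel, seed=seed, classifier_params=classifier_params,
        silhouette_cap=silhouette_cap, train_cap=train_cap,
    )
    return score, per_cluster


@dataclass
class ResolutionScan:
    """Scores over a resolution grid plus the elbow selection."""

    grid: np.ndarray
    scores: np.ndarray  # nan where no fold could be scored
    n_clusters: np.ndarray
    per_cluster: list[dict[int, float]]
    n_subjects: int
    labels: list[ClusterLabels] = field(default_factory=list)
    selected: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "resolution": self.grid,
            "score": self.scores,
            "n_clusters": self.n_clusters,
            "selected": [
                self.selected is not None and np.isclose(r, self.selected)
                for r in self.grid
            ],
        })

    def selected_labels(self) -> ClusterLabels:
        if self.selected is None:
            raise ValueError("no resolution selected yet")
        i = int(np.flatnonzero(np.isclose(self.grid, self.selected))[0])
        return self.labels[i]


def scan_resolutions(
    table: EventTable,
    panel: PanelConfig,
    grid=DEFAULT_GRID,
    k: int = DEFAULT_K,
    seed: int = 0,
    prune_threshold: float = DEFAULT_PRUNE,
    min_cells: int = DEFAULT_MIN_CELLS,
    classifier_params: dict | None = None,
    silhouette_cap: int = DEFAULT_SILHOUETTE_CAP,
    train_cap: int | None = None,
) -> ResolutionScan:
    """Score every resolution of the grid and select the elbow.

    The SNN graph is built once; partitions that repeat across
    resolutions reuse the memoized score.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) != len(np.unique(grid)):
        raise ValueError("resolution grid must be strictly increasing")
    graph = snn_jaccard(knn_neighbors(table, panel, k), prune_threshold)
    scores = np.full(len(grid), np.nan)
    n_clusters = np.zeros(len(grid), dtype=int)
    per_cluster: list[dict[int, float]] = []
    all_labels: list[ClusterLabels] = []
    cache: dict[bytes, tuple[float, dict[int, float]]] = {}
    for i, res in enumerate(grid):
        labels = filter_clusters(cluster_graph(graph, float(res), seed), min_cells)
        all_labels.append(labels)
        n_clusters[i] = labels.n_clusters
        key = labels.labels.tobytes()
        if key not in cache:
            score, pc, _ = cv_score_for_labels(
                table, labels, panel, seed=seed,
                classifier_params=classifier_params,
                silhouette_cap=silhouette_cap, train_cap=train_cap,
            )
            cache[key] = (score, pc)
            if np.isnan(score):
                logger.warning("resolution %.4f: all folds skipped", res)
        scores[i], pc = cache[key]
        per_cluster.append(pc)
    scan = ResolutionScan(
        grid=grid, scores=scores, n_clusters=n_clusters,
        per_cluster=per_cluster, n_subjects=len(table.subjects),
        labels=all_labels,
    )
    scan.selected = select_elbow(scan)
    return scan


def select_elbow(scan: ResolutionScan) -> float:
    """Elbow of the score curve: most negative second difference.

    Second differences are taken over the non-missing grid points (by
    grid index); ties break toward the smaller resolution. Curves with
    no concave corner (all second differences >= 0, e.g. linear or
    constant scores) fall back to the maximum-score grid point.
    """
    valid = np.flatnonzero(~np.isnan(scan.scores))
    if len(valid) < 3:
        raise ValueError("elbow selection needs at least 3 scored grid points")
    s = scan.scores[valid]
    d2 = s[2:] - 2 * s[1:-1] + s[:-2]
    # curvature below float noise does not count as a corner
    tol = 1e-9 * max(1.0, np.abs(s).max())
    if (d2 < -tol).any():
        pick = valid[1 + int(np.argmin(d2))]
    else:
        pick = valid[int(np.argmax(s))]
    return float(scan.grid[pick])
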