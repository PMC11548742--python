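"""Non-priori workload labeling.

Instead of pre-designed task phases or subjective scales, workload
levels are discovered from the data itself: the minute feature table is
standardized (z-score for numeric columns, one-hot for categorical
ones), projected onto two principal components, clustered with K-means
(K chosen by silhouette analysis over K = 2..6), and the two clusters
are mapped to {low, high} by temporal ordering — the cluster whose
minutes have the smaller median is the low-workload one, on the premise
that workload accumulates over a shift.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .indicators import INDICATOR_COLUMNS, SUBJECT_COLUMN, TIME_COLUMN

__all__ = [
    "preprocess_features",
    "preprocess_and_project",
    "select_cluster_count",
    "cluster_samples",
    "assign_workload_levels",
    "label_cohort",
]

DEFAULT_K_RANGE = (2, 6)
KMEANS_RESTARTS = 10

#: Categorical columns one-hot encoded for clustering when present. The
#: alarm flag is deliberately not among them: clustering runs on the
#: fatigue / eye-movement / respiration indicators plus subject
#: identity; the alarm joins the feature pool at the supervised stage.
CATEGORICAL_COLUMNS = [SUBJECT_COLUMN]


def preprocess_features(
    table: pd.DataFrame,
    include: Sequence[str] | None = None,
    include_time: bool = True,
    categoricals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Standardize the feature table for clustering.

    Numeric columns are z-scored; categorical (string) columns —
    subject identity by default — are one-hot encoded, with the dummies
    z-scored too so every column is on unit scale. Zero-variance columns
    are dropped with a warning. ``include`` restricts the numeric
    indicators used (default: all indicator columns present); the minute
    index joins as the ``time`` feature unless ``include_time`` is
    false.
    """
    if include is None:
        include = [c for c in INDICATOR_COLUMNS if c in table.columns]
    if categoricals is None:
        categoricals = CATEGORICAL_COLUMNS
    numeric = list(include)
    if include_time and TIME_COLUMN in table.columns and TIME_COLUMN not in numeric:
        numeric = [TIME_COLUMN] + numeric
    parts = [table[numeric].astype(float)]
    for col in categoricals:
        if col in table.columns:
            parts.append(pd.get_dummies(table[col].astype(str), prefix=col, dtype=float))
    x = pd.concat(parts, axis=1)
    sd = x.std(ddof=0)
    degenerate = sd[sd == 0.0].index.tolist()
    if degenerate:
        warnings.warn(f"dropping zero-variance columns: {degenerate}", stacklevel=2)
        x = x.drop(columns=degenerate)
        sd = sd.drop(index=degenerate)
    if x.shape[1] == 0:
        raise ValueError("all feature columns are constant")
    return (x - x.mean()) / sd


def preprocess_and_project(
    table: pd.DataFrame,
    include: Sequence[str] | None = None,
    include_time: bool = True,
) -> np.ndarray:
    """Standardize and project onto the top two principal components.

    Component signs are fixed by orienting each component so that its
    largest-magnitude loading is positive, removing PCA's sign
    indeterminacy.
    """
    x = preprocess_features(table, include=include, include_time=include_time)
    if len(x) < 3:
        raise ValueError("need at least 3 rows for projection")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 feature columns for a 2-D projection")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x.to_numpy())
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def select_cluster_count(
    coords: np.ndarray, k_range: tuple[int, int] = DEFAULT_K_RANGE, seed: int = 0
) -> int:
    """Pick K maximizing the mean silhouette of a seeded K-means fit.

    Silhouette uses Euclidean distance on the given coordinates; exact
    ties go to the smaller K.
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min < 2:
        raise ValueError("k_range lower bound must be >= 2")
    if len(coords) <= k_max:
        raise ValueError("need more rows than the largest candidate K")
    best_k, best_score = None, -np.inf
    for k in range(k_min, k_max + 1):
        labels = cluster_samples(coords, k, seed)
        score = silhouette_score(coords, labels, metric="euclidean")
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def cluster_samples(coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded K-means assignment with multiple restarts."""
    k = int(k)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(coords):
        raise ValueError("k cannot exceed the number of rows")
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=int(seed) & 0x7FFFFFFF)
    return km.fit_predict(np.asarray(coords, dtype=float))


def assign_workload_levels(assignments: np.ndarray, minutes: Sequence[int]) -> np.ndarray:
    """Map two clusters to {'low', 'high'} by temporal ordering.

    The cluster with the smaller median minute is the low-workload one
    (mean minute breaks an exact median tie). Invariant to cluster index
    permutation. Only the two-cluster case is supported.
    """
    assignments = np.asarray(assignments)
    minutes = np.asarray(minutes, dtype=float)
    ids = np.unique(assignments)
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(ids)}")
    stats = {
        c: (np.median(minutes[assignments == c]), np.mean(minutes[assignments == c]))
        for c in ids
    }
    low = min(ids, key=lambda c: stats[c])
    return np.where(assignments == low, "low", "high")


def label_cohort(
    table: pd.DataFrame,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    seed: int = 0,
    include: Sequence[str] | None = None,
    include_time: bool = True,
    use_full_matrix: bool = False,
) -> pd.DataFrame:
    """Run the full labeling stage over a minute feature table.

    Returns a copy of the table with ``cluster_id`` and
    ``workload_level`` columns appended. ``include`` restricts the
    indicators clustered on (e.g. the variance-prescreened set);
    ``use_full_matrix`` clusters on the full standardized matrix instead
    of the default 2-D principal component projection (sensitivity
    switch).
    """
    if use_full_matrix:
        coords = preprocess_features(table, include=include, include_time=include_time).to_numpy()
    else:
        coords = preprocess_and_project(table, include=include, include_time=include_time)
    k = select_cluster_count(coords, k_range=k_range, seed=seed)
    assignments = cluster_samples(coords, k, seed=seed)
    levels = assign_workload_levels(assignments, table[TIME_COLUMN])
    out = table.copy()
    out["cluster_id"] = assignments
    out["workload_level"] = levels
    return out
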