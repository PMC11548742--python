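"""Supervised feature stage.

With workload levels in hand (from clustering), this stage measures
which indicators actually carry the workload signal and how feature
sets built from them classify:

1. a coefficient-of-variation prescreen removes sensor channels that
   barely moved during the task (fatigue metrics are always kept);
2. a seeded random forest fit on an 80% training split yields
   normalized feature importances c_i;
3. screening at an importance threshold (0.010 for the wide set, 0.040
   for the narrow one, inclusive) yields the raw feature sets;
4. per-subject running cumulative sums of the wide set's features form
   the cumulative feature set, which encodes workload accumulation;
5. a bank of ten classifiers — six bases (SVM, DT, RF, LR, KNN, NN)
   and four ensembles (hard Voting, Stacking with a logistic
   meta-learner, Bagging of the best base, gradient Boosting) — is
   grid-searched and scored by 5-fold cross-validation plus a 20%
   holdout; the whole procedure repeats 10 times with distinct seeds
   and the modal accuracy pair (rounded to 3 decimals) is reported per
   algorithm.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
    VotingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .indicators import (
    FATIGUE_COLUMNS,
    INDICATOR_COLUMNS,
    SUBJECT_COLUMN,
    TIME_COLUMN,
)

__all__ = [
    "FeatureSet",
    "BankConfig",
    "ALGORITHMS",
    "prescreen_low_variance",
    "rank_feature_importance",
    "screen_features",
    "build_cumulative_set",
    "evaluate_classifier_bank",
]

SCREEN_THRESHOLD_WIDE = 0.010
SCREEN_THRESHOLD_NARROW = 0.040
CUMULATIVE_PREFIX = "cum_"

ALGORITHMS = ["SVM", "DT", "RF", "LR", "KNN", "NN", "Voting", "Stacking", "Bagging", "Boosting"]
_BASE_ALGORITHMS = ["SVM", "DT", "RF", "LR", "KNN", "NN"]


@dataclass(frozen=True)
class FeatureSet:
    """A named list of feature columns, raw or cumulative."""

    name: str
    columns: tuple[str, ...]
    mode: str = "raw"  # "raw" | "cumulative"

    def __post_init__(self):
        if self.mode not in ("raw", "cumulative"):
            raise ValueError("mode must be 'raw' or 'cumulative'")


@dataclass(frozen=True)
class BankConfig:
    """Evaluation protocol for the classifier bank."""

    seed: int = 0
    n_repeats: int = 10
    test_size: float = 0.2
    cv_folds: int = 5
    algorithms: tuple[str, ...] = tuple(ALGORITHMS)


def prescreen_low_variance(
    table: pd.DataFrame,
    threshold: float = 0.05,
    always_keep: Sequence[str] = tuple(FATIGUE_COLUMNS),
) -> list[str]:
    """Drop indicators whose coefficient of variation falls below ``threshold``.

    The CV is sd/|mean| over the whole session; channels that barely vary
    carry no workload signal. Fatigue metrics are exempt and always
    retained. Returns the retained indicator columns in canonical order.
    """
    if len(table) == 0:
        raise ValueError("table is empty")
    retained = []
    for col in INDICATOR_COLUMNS:
        if col not in table.columns:
            continue
        if col in always_keep:
            retained.append(col)
            continue
        x = table[col].to_numpy(dtype=float)
        mean = np.mean(x)
        sd = np.std(x)
        cv = np.inf if mean == 0 and sd > 0 else (0.0 if sd == 0 else sd / abs(mean))
        if cv >= threshold:
            retained.append(col)
    return retained


def _design_matrix(
    table: pd.DataFrame, feature_columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Numeric design matrix: time + indicators + subject/alarm dummies."""
    if feature_columns is None:
        feature_columns = [TIME_COLUMN] + [c for c in INDICATOR_COLUMNS if c in table.columns]
    parts = []
    for col in feature_columns:
        if col == SUBJECT_COLUMN:
            parts.append(pd.get_dummies(table[col].astype(str), prefix=SUBJECT_COLUMN, dtype=float))
        elif col == "alarm":
            parts.append(table[col].astype(float).rename("alarm"))
        else:
            parts.append(table[col].astype(float))
    return pd.concat(parts, axis=1)


def rank_feature_importance(
    table: pd.DataFrame,
    labels: Sequence,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
    test_size: float = 0.2,
    n_estimators: int = 300,
) -> pd.Series:
    """Random-forest feature importances, normalized to sum 1.

    The forest is fit on a seeded 80% training split (the held-out 20%
    matches the split later used for classifier comparison); importances
    are impurity-based, returned sorted descending. By default the
    feature matrix holds the minute index, all indicator columns present,
    and one-hot subject / alarm dummies.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain two classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per class")
    if feature_columns is None:
        feature_columns = (
            [TIME_COLUMN]
            + [c for c in INDICATOR_COLUMNS if c in table.columns]
            + [c for c in (SUBJECT_COLUMN, "alarm") if c in table.columns]
        )
    x = _design_matrix(table, feature_columns)
    seed = int(seed) & 0x7FFFFFFF
    x_train, _, y_train, _ = train_test_split(
        x, y, test_size=test_size, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(x_train, y_train)
    # subject one-hot dummies keep their own (small) importances, so the
    # screening step judges each of them individually
    weights = pd.Series(forest.feature_importances_, index=x.columns, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate forest: zero total importance")
    weights = weights / total
    return weights.sort_values(ascending=False, kind="mergesort")


def screen_features(weights: Mapping[str, float] | pd.Series, threshold: float) -> FeatureSet:
    """Retain indicators with importance >= ``threshold`` (inclusive).

    Returns a raw-mode :class:`FeatureSet` ordered by descending
    importance. Raising the threshold never adds a feature.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    w = pd.Series(dict(weights), dtype=float)
    kept = w[w >= threshold].sort_values(ascending=False, kind="mergesort")
    return FeatureSet(name=f"ge_{threshold:g}", columns=tuple(kept.index), mode="raw")


def build_cumulative_set(
    table: pd.DataFrame, base: FeatureSet
) -> tuple[pd.DataFrame, FeatureSet]:
    """Per-subject running cumulative sums of a base feature set.

    The table must be sorted by (subject, minute). Each base column
    gains a ``cum_``-prefixed counterpart holding its cumulative sum
    over the subject's session; the returned cumulative-mode
    :class:`FeatureSet` lists exactly those columns.
    """
    by_subject = table.groupby(SUBJECT_COLUMN)[TIME_COLUMN]
    if not by_subject.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("table must be sorted by (subject_id, minute)")
    out = table.copy()
    cum_cols = []
    for col in base.columns:
        cum_col = CUMULATIVE_PREFIX + col
        out[cum_col] = out.groupby(SUBJECT_COLUMN)[col].cumsum()
        cum_cols.append(cum_col)
    return out, FeatureSet(name=base.name + "_cumulative", columns=tuple(cum_cols), mode="cumulative")


# ---------------------------------------------------------------------------
# classifier bank


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def _base_grids(seed: int) -> dict[str, tuple[Pipeline, dict]]:
    """The six base algorithms with small fixed hyperparameter grids."""
    return {
        "SVM": (_scaled(SVC(random_state=seed)), {"model__C": [0.1, 1.0, 10.0]}),
        "DT": (
            _scaled(DecisionTreeClassifier(random_state=seed)),
            {"model__max_depth": [3, 5, None]},
        ),
        "RF": (
            _scaled(RandomForestClassifier(n_estimators=100, random_state=seed)),
            {"model__max_depth": [3, None]},
        ),
        "LR": (
            _scaled(LogisticRegression(max_iter=2000, random_state=seed)),
            {"model__C": [0.1, 1.0, 10.0]},
        ),
        "KNN": (_scaled(KNeighborsClassifier()), {"model__n_neighbors": [3, 5, 7]}),
        "NN": (
            # lbfgs: full-batch quasi-Newton, far more reliable than SGD
            # variants at a few hundred samples
            _scaled(MLPClassifier(solver="lbfgs", max_iter=2000, random_state=seed)),
            {"model__hidden_layer_sizes": [(16,), (32,)]},
        ),
    }


def _evaluate_once(
    x: pd.DataFrame, y: np.ndarray, config: BankConfig, seed: int
) -> dict[str, tuple[float, float]]:
    """One repeat: 20% holdout + grid search + 5-fold CV per algorithm."""
    x_train, x_test, y_train, y_test = train_test_split(
        x, y, test_size=config.test_size, random_state=seed, stratify=y
    )
    _, counts = np.unique(y_train, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError("fold count exceeds the size of the smallest class")

    results: dict[str, tuple[float, float]] = {}
    best_estimators: dict[str, Pipeline] = {}
    best_cv: dict[str, float] = {}
    for name, (pipe, grid) in _base_grids(seed).items():
        search = GridSearchCV(pipe, grid, cv=config.cv_folds, scoring="accuracy", n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(x_train, y_train)
        best_estimators[name] = search.best_estimator_
        best_cv[name] = float(search.best_score_)
        if name in config.algorithms:
            results[name] = (best_cv[name], float(search.best_estimator_.score(x_test, y_test)))

    bases = [(n, clone(best_estimators[n])) for n in _BASE_ALGORITHMS]
    best_base = max(_BASE_ALGORITHMS, key=lambda n: best_cv[n])
    ensembles = {
        "Voting": VotingClassifier(estimators=bases, voting="hard"),
        "Stacking": StackingClassifier(
            estimators=bases,
            final_estimator=LogisticRegression(max_iter=2000),
            cv=config.cv_folds,
        ),
        "Bagging": BaggingClassifier(
            estimator=clone(best_estimators[best_base]), n_estimators=10, random_state=seed
        ),
        "Boosting": _scaled(GradientBoostingClassifier(random_state=seed)),
    }
    for name, est in ensembles.items():
        if name not in config.algorithms:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_acc = float(
                np.mean(
                    cross_val_score(
                        clone(est), x_train, y_train, cv=config.cv_folds, scoring="accuracy"
                    )
                )
            )
            est.fit(x_train, y_train)
        results[name] = (cv_acc, float(est.score(x_test, y_test)))
    return results


def _modal_pair(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """Highest-frequency (cv, test) pair after rounding to 3 decimals.

    Frequency ties are broken toward the repeat order's median: among
    tied pairs, the one whose occurrences lie closest to the middle
    repeat wins.
    """
    rounded = [(round(c, 3), round(t, 3)) for c, t in pairs]
    freq = Counter(rounded)
    top = max(freq.values())
    candidates = [p for p, n in freq.items() if n == top]
    if len(candidates) == 1:
        return candidates[0]
    mid = (len(rounded) - 1) / 2.0
    def median_distance(pair):
        positions = [i for i, p in enumerate(rounded) if p == pair]
        return (abs(float(np.median(positions)) - mid), pair)
    return min(candidates, key=median_distance)


def evaluate_classifier_bank(
    table: pd.DataFrame,
    labels: Sequence,
    feature_set: FeatureSet,
    config: BankConfig = BankConfig(),
) -> pd.DataFrame:
    """Score the classifier bank on one feature set.

    Returns a report indexed by algorithm with ``cv_accuracy`` and
    ``test_accuracy`` columns: per repeat, a seeded 20% stratified
    holdout is drawn, each base algorithm is grid-searched with
    ``cv_folds``-fold cross-validation on the training split and scored
    on the holdout, and the four ensembles are built over the tuned
    bases; over ``n_repeats`` repeats the modal accuracy pair per
    algorithm is reported.
    """
    missing = [c for c in feature_set.columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns not in table: {missing}")
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    x = table[list(feature_set.columns)].astype(float)
    root = int(config.seed) & 0x7FFFFFFF
    per_algorithm: dict[str, list[tuple[float, float]]] = {a: [] for a in config.algorithms}
    for r in range(config.n_repeats):
        rep = _evaluate_once(x, y, config, (root + 7919 * r) & 0x7FFFFFFF)
        for a in config.algorithms:
            per_algorithm[a].append(rep[a])
    rows = {a: _modal_pair(per_algorithm[a]) for a in config.algorithms}
    report = pd.DataFrame.from_dict(rows, orient="index", columns=["cv_accuracy", "test_accuracy"])
    report.index.name = "algorithm"
    return report
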