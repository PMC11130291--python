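"""Random-forest regression of hypoxia on features, with importance ranking.

Forests (1000 trees, mtry = sqrt of the feature count, squared-error
impurity) are refit on each of 10 cross-validation folds of the balanced
patch set; each fold's mean-decrease-in-impurity scores are kept per run so
both "top score in k of 10 runs" statements and mean rankings can be
computed.  Scores are normalized to sum 1 per run, making fractional cutoffs
(one fourth / one third of a run's top score) scale-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)


@dataclass
class RFConfig:
    n_trees: int = 1000
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ImportanceTable:
    """Feature x cv-run matrix of normalized impurity importances."""

    scores: np.ndarray
    feature_labels: np.ndarray
    val_r2: np.ndarray | None = None  # held-out-fold R2 per CV run
    n_obs: int = 0  # balanced observations the forests were fit on

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a feature x run matrix")
        if len(self.feature_labels) != self.scores.shape[0]:
            raise ValueError("one label per feature row required")
        if np.any(self.scores < 0):
            raise ValueError("importances must be nonnegative")

    @property
    def mean_scores(self) -> np.ndarray:
        return self.scores.mean(axis=1)


def fit_importance(X: np.ndarray, y: np.ndarray, config: RFConfig,
                   feature_labels: np.ndarray | None = None) -> ImportanceTable:
    """One forest per CV fold; per-run impurity importances, seeded.

    ``X``: N x F feature matrix (latent patch means or original channel
    patch means), ``y``: N continuous hypoxia targets in [0,1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("X must be N x F with one target per row")
    if len(X) < config.cv_folds:
        raise ValueError("fewer observations than CV folds")
    if np.ptp(y) == 0:
        warnings.warn("constant regression target: importances are degenerate",
                      stacklevel=2)
    if feature_labels is None:
        feature_labels = np.arange(X.shape[1])
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    runs, r2s = [], []
    rng = np.random.default_rng(config.seed)
    for train_idx, test_idx in kf.split(X):
        forest = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features="sqrt",
            criterion="squared_error",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X[train_idx], y[train_idx])
        imp = forest.feature_importances_
        total = imp.sum()
        runs.append(imp / total if total > 0 else imp)
        if np.ptp(y[test_idx]) > 0:
            r2s.append(forest.score(X[test_idx], y[test_idx]))
        else:
            r2s.append(np.nan)
    return ImportanceTable(
        np.column_stack(runs),
        np.asarray(feature_labels),
        val_r2=np.asarray(r2s),
        n_obs=len(X),
    )


def top_latent_feature(table: ImportanceTable) -> int:
    """Index of the feature with the highest mean score (ties: lowest index)."""
    if table.scores.size == 0:
        raise ValueError("empty importance table")
    mean = table.mean_scores
    top = int(np.argmax(mean))
    if np.sum(mean == mean[top]) > 1:
        log.info("importance tie at %.6g; choosing lowest index %d", mean[top], top)
    return top


def select_rf_features(table: ImportanceTable, fraction: float = 0.25) -> np.ndarray:
    """Union over runs of features scoring >= fraction of the run's top score."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    selected = np.zeros(table.scores.shape[0], dtype=bool)
    for r in range(table.scores.shape[1]):
        col = table.scores[:, r]
        if col.max() <= 0:
            continue
        selected |= col >= fraction * col.max()
    return np.asarray(table.feature_labels)[selected]
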