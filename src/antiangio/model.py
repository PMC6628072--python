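"""Random-forest classifier: training, tuning, persistence, prediction.

The forest itself is scikit-learn's bagged-CART ensemble; this module owns
the contracts the surrounding protocol needs: a vote-fraction score (the
fraction of trees calling a peptide anti-angiogenic, so ``ntree * score``
is always an integer), a documented tie-break at the decision threshold
(ties go negative), per-sample out-of-bag bookkeeping, and refusal to
predict when the feature-name manifest does not match the training matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_sample_indices, _get_n_samples_bootstrap

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Hyper-parameter search grids of the tuning protocol.
NTREE_GRID: tuple[int, ...] = (100, 200, 300, 400, 500)
MTRY_GRID: tuple[int, ...] = tuple(range(1, 11))


class ModelError(ValueError):
    """Invalid training input or feature-manifest mismatch."""


@dataclass(frozen=True)
class RFConfig:
    """Forest hyper-parameters.

    ``mtry=None`` resolves to floor(sqrt(n_features)) at fit time (the
    classical classification default).  ``decision_threshold`` is the vote
    fraction strictly above which a peptide is called positive.
    """

    ntree: int = 100
    mtry: Optional[int] = None
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if not (0 < self.decision_threshold < 1):
            raise ValueError("decision_threshold must be in (0, 1)")

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry is None:
            return max(1, int(np.floor(np.sqrt(n_features))))
        if self.mtry > n_features:
            raise ValueError(f"mtry={self.mtry} exceeds feature count {n_features}")
        return self.mtry


@dataclass
class TrainedModel:
    """A fitted forest plus the manifest needed to apply it safely."""

    config: RFConfig
    feature_names: tuple[str, ...]
    estimator: RandomForestClassifier
    n_training_samples: int
    format_version: int = MODEL_FORMAT_VERSION

    # -- prediction ---------------------------------------------------------

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [n for n in self.feature_names if n not in X.columns]
        extra = [n for n in X.columns if n not in self.feature_names]
        if missing or extra:
            raise ModelError(
                f"feature mismatch: missing {missing[:5]}{'...' if len(missing) > 5 else ''}, "
                f"extra {extra[:5]}{'...' if len(extra) > 5 else ''}")
        return X[list(self.feature_names)]

    def vote_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting positive, per sample."""
        X = self._check_features(X)
        if X.isna().any().any():
            raise ModelError("feature matrix contains NaN")
        arr = X.to_numpy()
        votes = np.zeros(len(X))
        for tree in self.estimator.estimators_:
            votes += tree.predict(arr) == 1
        return votes / len(self.estimator.estimators_)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-sample score and call.

        ``call`` is positive iff score is strictly greater than the decision
        threshold; a score exactly at the threshold is called negative.
        """
        scores = self.vote_scores(X)
        calls = np.where(scores > self.config.decision_threshold, "positive", "negative")
        return pd.DataFrame({"score": scores, "call": calls}, index=X.index)

    # -- out-of-bag bookkeeping ---------------------------------------------

    def oob_matrix(self) -> np.ndarray:
        """Boolean (n_trees, n_train) matrix: True where sample was out-of-bag."""
        n = self.n_training_samples
        try:
            n_boot = _get_n_samples_bootstrap(n, self.estimator.max_samples, None)
        except TypeError:  # older signature without sample_weight
            n_boot = _get_n_samples_bootstrap(n, self.estimator.max_samples)
        mask = np.ones((len(self.estimator.estimators_), n), dtype=bool)
        for t, tree in enumerate(self.estimator.estimators_):
            try:
                sampled = _generate_sample_indices(tree.random_state, n, n_boot, None)
            except TypeError:
                sampled = _generate_sample_indices(tree.random_state, n, n_boot)
            mask[t, sampled] = False
        return mask

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": self.format_version,
            "config": self.config,
            "feature_names": self.feature_names,
            "estimator": self.estimator,
            "n_training_samples": self.n_training_samples,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ModelError(f"unsupported model format version {version!r} "
                             f"(expected {MODEL_FORMAT_VERSION})")
        return cls(config=payload["config"],
                   feature_names=tuple(payload["feature_names"]),
                   estimator=payload["estimator"],
                   n_training_samples=payload["n_training_samples"],
                   format_version=version)


def train(X: pd.DataFrame, y: Sequence[int] | pd.Series, config: RFConfig) -> TrainedModel:
    """Fit a bagged-CART forest on a labeled feature matrix.

    ``y`` is 0/1 with 1 = positive (anti-angiogenic).  Trees are fully
    grown (no pruning), each on a bootstrap sample of the training set;
    the one-third or so left out of each bootstrap is retained as that
    tree's out-of-bag set.  Deterministic under ``config.seed``.
    """
    y = np.asarray(y)
    if X.isna().any().any():
        raise ModelError("feature matrix contains NaN")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError("training labels contain a single class")
    if counts.min() < 2:
        raise ModelError("need at least 2 samples per class")
    clf = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.resolve_mtry(X.shape[1]),
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(X.to_numpy(), y)
    return TrainedModel(config=config,
                        feature_names=tuple(X.columns),
                        estimator=clf,
                        n_training_samples=len(X))


def tune(
    X: pd.DataFrame,
    y: Sequence[int] | pd.Series,
    ntree_grid: Sequence[int] = NTREE_GRID,
    mtry_grid: Sequence[int] = MTRY_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[RFConfig, pd.DataFrame]:
    """Grid-search ntree x mtry by mean k-fold CV accuracy.

    mtry values exceeding the feature count are skipped with a warning.
    Ties prefer smaller ntree, then smaller mtry.  Returns the winning
    config and the full grid trace.
    """
    from .evaluate import kfold_cv_matrix

    records = []
    n_features = X.shape[1]
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            if mtry > n_features:
                logger.warning("tune: skipping mtry=%d (> %d features)", mtry, n_features)
                continue
            config = RFConfig(ntree=ntree, mtry=mtry, seed=seed)
            result = kfold_cv_matrix(X, pd.Series(np.asarray(y), index=X.index),
                                     config, k=folds, seed=seed)
            records.append({"ntree": ntree, "mtry": mtry, "cv_accuracy": result.ac})
    if not records:
        raise ModelError("empty tuning grid after skipping infeasible mtry values")
    trace = pd.DataFrame(records)
    best = trace.sort_values(["cv_accuracy", "ntree", "mtry"],
                             ascending=[False, True, True]).iloc[0]
    config = RFConfig(ntree=int(best["ntree"]), mtry=int(best["mtry"]), seed=seed)
    logger.info("tune: best ntree=%d mtry=%d (CV acc %.4f)",
                config.ntree, config.mtry, best["cv_accuracy"])
    return config, trace
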