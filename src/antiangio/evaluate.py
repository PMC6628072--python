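"""Performance evaluation: confusion metrics, ROC/AUC, k-fold CV and the
repeated random-split experiment protocol.

Threshold metrics are accuracy, sensitivity, specificity and the Matthews
correlation coefficient:

    Ac  = (TP + TN) / (TP + TN + FP + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 whenever a denominator factor vanishes.  The ROC is a
threshold sweep over the distinct vote scores (equal scores grouped) with
trapezoidal area; 1 is a perfect classifier, 0.5 a random one.

Cross-validation pools all out-of-fold predictions into a single confusion
table before computing metrics, so a k-fold run yields one metric set; the
jackknife is the k = n limit.  The experiment protocol draws ``rounds``
stratified train/test splits, reports per-round CV (on the training set)
and independent-test metrics, and aggregates them as mean and SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import features as _features
from .model import RFConfig, TrainedModel, train as _train, tune as _tune
from .seqio import Dataset, SplitPlan, make_splits

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Threshold metrics plus (optionally) the ROC curve and its area."""

    ac: float
    sn: float
    sp: float
    mcc: float
    auroc: Optional[float] = None
    roc_points: Optional[tuple[tuple[float, float], ...]] = None
    counts: Optional[ConfusionCounts] = None

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        d = {"Ac": self.ac * scale, "Sn": self.sn * scale, "Sp": self.sp * scale,
             "MCC": self.mcc}
        if self.auroc is not None:
            d["auROC"] = self.auroc
        return d


def confusion(calls: Sequence, labels: Sequence) -> ConfusionCounts:
    """Cross-tabulate predicted calls against true labels (1/'positive' = positive)."""
    if len(calls) != len(labels):
        raise EvaluationError(f"length mismatch: {len(calls)} calls vs "
                              f"{len(labels)} labels")

    def as_bool(x) -> bool:
        if isinstance(x, str):
            return x == "positive"
        return bool(x)

    tp = tn = fp = fn = 0
    for c, l in zip(calls, labels):
        c, l = as_bool(c), as_bool(l)
        if c and l:
            tp += 1
        elif not c and not l:
            tn += 1
        elif c and not l:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity and MCC from a confusion table."""
    if c.total == 0:
        raise EvaluationError("empty confusion table")
    ac = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return MetricSet(ac=ac, sn=sn, sp=sp, mcc=mcc, counts=c)


def roc_auc(scores: Sequence[float], labels: Sequence) -> tuple[
        tuple[tuple[float, float], ...], float]:
    """ROC points (FPR, TPR) from a descending threshold sweep, and the
    trapezoidal area under them.  Equal scores are grouped, so ties move
    along the diagonal and an all-ties score set yields exactly 0.5."""
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if (l == "positive" or l == 1 or l is True) else 0 for l in labels])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += y[order[j]]
            fp += 1 - y[order[j]]
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return tuple(map(tuple, pts)), auc


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Index partition into k folds, class-balanced by round-robin assignment."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return [np.array(sorted(f)) for f in folds if len(f)]


def kfold_cv_matrix(
    X: pd.DataFrame,
    y: pd.Series,
    config: RFConfig,
    k: int = 5,
    seed: int = 0,
) -> MetricSet:
    """Pooled k-fold CV on an encoded matrix.

    Folds are stratified (k = n gives the jackknife); every sample is
    predicted exactly once out-of-fold, all predictions are pooled into one
    confusion table and one ROC.  Deterministic under ``seed``.
    """
    yv = np.asarray(y)
    n = len(X)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if k != n:
        smallest = int(np.bincount(yv).min())
        if k > smallest:
            raise EvaluationError(f"k={k} exceeds smallest class size {smallest} "
                                  "(use k = n for the jackknife)")
    folds = _stratified_folds(yv, k, seed)
    scores = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = _train(X.iloc[mask], yv[mask], config)
        scores[fold] = model.vote_scores(X.iloc[fold])
    calls = scores > config.decision_threshold
    m = metrics(confusion(calls, yv))
    roc_points, auc = roc_auc(scores, yv)
    return MetricSet(ac=m.ac, sn=m.sn, sp=m.sp, mcc=m.mcc,
                     auroc=auc, roc_points=roc_points, counts=m.counts)


def kfold_cv(
    dataset: Dataset,
    combination: str | Sequence[str],
    config: Optional[RFConfig] = None,
    k: int = 5,
    seed: int = 0,
    **encode_kwargs,
) -> MetricSet:
    """Encode a labeled dataset and run pooled stratified k-fold CV."""
    dataset.require_labels()
    X, y = _features.feature_matrix(dataset, combination, **encode_kwargs)
    return kfold_cv_matrix(X, y, config or RFConfig(seed=seed), k=k, seed=seed)


# ---------------------------------------------------------------------------
# Repeated random-split experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSummary:
    """Per-round CV and independent-test metrics for one feature combination."""

    combination: str
    cv_rounds: list[MetricSet] = field(default_factory=list)
    test_rounds: list[MetricSet] = field(default_factory=list)

    @staticmethod
    def _aggregate(rounds: list[MetricSet], phase: str) -> pd.DataFrame:
        rows = [m.as_dict(percent=True) for m in rounds]
        df = pd.DataFrame(rows)
        out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1) if len(df) > 1
                            else pd.Series(0.0, index=df.columns)})
        out.insert(0, "phase", phase)
        return out

    def summary(self) -> pd.DataFrame:
        """Mean and SD per metric (Ac/Sn/Sp as percent) for CV and test phases."""
        return pd.concat([self._aggregate(self.cv_rounds, "cv"),
                          self._aggregate(self.test_rounds, "test")])

    def mean_test(self, metric: str) -> float:
        return float(np.mean([m.as_dict()[metric] for m in self.test_rounds]))

    def mean_cv(self, metric: str) -> float:
        return float(np.mean([m.as_dict()[metric] for m in self.cv_rounds]))

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for phase, rounds in (("cv", self.cv_rounds), ("test", self.test_rounds)):
            for i, m in enumerate(rounds, start=1):
                rows.append({"feature_set": self.combination, "round": i,
                             "phase": phase, "Ac": m.ac, "Sn": m.sn, "Sp": m.sp,
                             "MCC": m.mcc, "auROC": m.auroc})
        return pd.DataFrame(rows)


def run_experiment(
    dataset: Dataset,
    combinations: Sequence[str] = ("AAC",),
    rounds: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
    config: Optional[RFConfig] = None,
    tune_per_round: bool = False,
    cv_folds: int = 5,
    pse_params: Optional[_features.PseParams] = None,
    am_params: Optional[_features.PseParams] = None,
    table: Optional[_features.PropertyTable] = None,
    standardize: bool = True,
) -> dict[str, ExperimentSummary]:
    """The repeated random-split evaluation protocol.

    For each round: draw a stratified train/test split, optionally tune
    ntree/mtry on the training set, train the forest, score it by pooled
    k-fold CV on the training set and by the held-out independent test set.
    Returns one :class:`ExperimentSummary` per feature combination.
    """
    dataset.require_labels()
    pse_params = pse_params or _features.PseParams()
    base_config = config or RFConfig(seed=seed)
    plans = make_splits(dataset, rounds=rounds, train_fraction=train_fraction,
                        seed=seed)
    results: dict[str, ExperimentSummary] = {}
    for combo in combinations:
        X, y = _features.feature_matrix(dataset, combo, pse_params=pse_params,
                                        am_params=am_params, table=table,
                                        standardize=standardize)
        summary = ExperimentSummary(combination=combo if isinstance(combo, str)
                                    else "+".join(combo))
        for plan in plans:
            train_ids, test_ids = list(plan.train_ids), list(plan.test_ids)
            X_train, y_train = X.loc[train_ids], y.loc[train_ids]
            X_test, y_test = X.loc[test_ids], y.loc[test_ids]
            round_config = RFConfig(ntree=base_config.ntree, mtry=base_config.mtry,
                                    seed=plan.seed,
                                    decision_threshold=base_config.decision_threshold)
            if tune_per_round:
                tuned, _ = _tune(X_train, y_train, folds=cv_folds, seed=plan.seed)
                round_config = tuned
            summary.cv_rounds.append(
                kfold_cv_matrix(X_train, y_train, round_config, k=cv_folds,
                                seed=plan.seed))
            model = _train(X_train, y_train, round_config)
            scores = model.vote_scores(X_test)
            calls = scores > round_config.decision_threshold
            m = metrics(confusion(calls, np.asarray(y_test)))
            roc_points, auc = roc_auc(scores, np.asarray(y_test))
            summary.test_rounds.append(
                MetricSet(ac=m.ac, sn=m.sn, sp=m.sp, mcc=m.mcc, auroc=auc,
                          roc_points=roc_points, counts=m.counts))
        results[summary.combination] = summary
        logger.info("experiment %s: mean test Ac %.2f%%, MCC %.2f",
                    summary.combination, summary.mean_test("Ac") * 100,
                    summary.mean_test("MCC"))
    return results


def summary_table(results: dict[str, ExperimentSummary]) -> pd.DataFrame:
    """Tidy mean +/- SD table (percent metrics to 2 decimals) across combinations."""
    rows = []
    for name, summary in results.items():
        for phase, rounds in (("5-fold CV", summary.cv_rounds),
                              ("independent test", summary.test_rounds)):
            stats = pd.DataFrame([m.as_dict(percent=True) for m in rounds])
            mean, sd = stats.mean(), stats.std(ddof=1) if len(stats) > 1 else 0.0
            row = {"feature_set": name, "phase": phase}
            for col in stats.columns:
                m = mean[col]
                s = float(sd[col]) if len(stats) > 1 else 0.0
                row[col] = f"{m:.2f} ± {s:.2f}"
            rows.append(row)
    return pd.DataFrame(rows)
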