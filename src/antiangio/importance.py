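"""Feature-importance and compositional characterization of peptide classes.

The importance protocol averages the forest's mean decrease of Gini index
(MDGI) over an ensemble of forests grown with a fixed schedule of mtry
values (2, 3, 5, 7, 9, 11, 13, 15, 17, 20) at 100 trees each, which damps
the dependence of impurity importance on the feature-subsampling rate.
MDGI for one forest is the total Gini-impurity decrease attributable to
splits on a feature, weighted by the number of samples reaching each
split and averaged over trees; values are reported on the
training-set-size scale used by the classical R implementation, so they
are comparable across forests of the same n.

The compositional analyses are classical: per-residue class-mean
composition differences with a Welch two-sample test, and per-position
residue-frequency matrices for the first/last N residues (the numeric
backbone of a sequence logo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AMINO_ACIDS, THREE_LETTER
from .model import RFConfig, train as _train
from .seqio import Dataset, NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

#: The fixed mtry schedule of the importance-averaging protocol.
MTRY_SCHEDULE: tuple[int, ...] = (2, 3, 5, 7, 9, 11, 13, 15, 17, 20)


class ImportanceError(ValueError):
    pass


def gini(probabilities: Sequence[float]) -> float:
    """Gini impurity 1 - sum_c p(c|t)^2 of a tree node."""
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ImportanceError("node class probabilities must be a simplex")
    return float(1.0 - np.sum(p ** 2))


def _forest_mdgi(model) -> np.ndarray:
    """Per-feature MDGI of one forest on the R-style scale.

    Each tree's unnormalized impurity decrease (per training sample) is
    rescaled by the training-set size and averaged over trees; non-negative
    by construction.
    """
    per_tree = np.array([
        tree.tree_.compute_feature_importances(normalize=False)
        for tree in model.estimator.estimators_
    ])
    return per_tree.mean(axis=0) * model.n_training_samples


@dataclass
class ImportanceReport:
    """Averaged MDGI per feature with per-run values and ranks."""

    table: pd.DataFrame  # index: feature; columns: mdgi, rank, run_1..run_k
    mtry_schedule: tuple[int, ...]
    ntree: int
    seed: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("rank").head(n)

    def rank_of(self, feature: str) -> int:
        return int(self.table.loc[feature, "rank"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def mdgi_profile(
    X: pd.DataFrame,
    y: pd.Series | Sequence[int],
    mtry_schedule: Sequence[int] = MTRY_SCHEDULE,
    ntree: int = 100,
    seed: int = 0,
) -> ImportanceReport:
    """Average MDGI over one forest per mtry value in the schedule.

    Schedule entries above the feature count are clamped with a warning.
    Each forest gets a distinct deterministic seed derived from ``seed``,
    so the whole report is reproducible.  Ranks: 1 = largest mean MDGI,
    ties broken by feature order.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ImportanceError("importance requires both classes in the labels")
    n_features = X.shape[1]
    schedule = []
    for m in mtry_schedule:
        if m > n_features:
            logger.warning("mdgi_profile: clamping mtry=%d to %d features",
                           m, n_features)
            m = n_features
        schedule.append(m)

    runs = np.zeros((len(schedule), n_features))
    for i, mtry in enumerate(schedule):
        config = RFConfig(ntree=ntree, mtry=mtry, seed=(seed * 131 + i) % (2 ** 31))
        model = _train(X, y, config)
        runs[i] = _forest_mdgi(model)

    mean = runs.mean(axis=0)
    order = np.lexsort((np.arange(n_features), -mean))
    rank = np.empty(n_features, dtype=int)
    rank[order] = np.arange(1, n_features + 1)
    table = pd.DataFrame({"mdgi": mean, "rank": rank}, index=X.columns)
    for i in range(len(schedule)):
        table[f"run_{i + 1}"] = runs[i]
    return ImportanceReport(table=table, mtry_schedule=tuple(schedule),
                            ntree=ntree, seed=seed)


def composition_diff(dataset: Dataset, test: str = "welch") -> pd.DataFrame:
    """Per-residue composition contrast between classes.

    For every residue the per-peptide composition fraction is averaged
    within each class; the difference is positive-class mean minus
    negative-class mean, ranked by absolute magnitude (rank 1 = largest).
    Significance is a two-sided Welch two-sample test on the per-peptide
    fractions (``test='welch'``, the default) or Student's pooled-variance
    variant (``test='student'``).
    """
    if test not in ("welch", "student"):
        raise ImportanceError(f"unknown test {test!r}")
    dataset.require_labels()
    pos = [p.sequence for p in dataset if p.label == POSITIVE]
    neg = [p.sequence for p in dataset if p.label == NEGATIVE]

    def fractions(seqs: list[str]) -> np.ndarray:
        out = np.zeros((len(seqs), 20))
        for i, s in enumerate(seqs):
            for c in s:
                out[i, AMINO_ACIDS.index(c)] += 1
            out[i] /= len(s)
        return out

    fp, fn = fractions(pos), fractions(neg)
    mean_pos, mean_neg = fp.mean(axis=0), fn.mean(axis=0)
    diff = mean_pos - mean_neg
    pvals = np.ones(20)
    for j in range(20):
        if fp[:, j].std() == 0 and fn[:, j].std() == 0:
            pvals[j] = 1.0 if diff[j] == 0 else 0.0
            continue
        _, pvals[j] = stats.ttest_ind(fp[:, j], fn[:, j],
                                      equal_var=(test == "student"))
    order = np.lexsort((np.arange(20), -np.abs(diff)))
    rank = np.empty(20, dtype=int)
    rank[order] = np.arange(1, 21)
    return pd.DataFrame({
        "residue": list(AMINO_ACIDS),
        "name": [THREE_LETTER[aa] for aa in AMINO_ACIDS],
        "mean_positive": mean_pos,
        "mean_negative": mean_neg,
        "difference": diff,
        "p_value": pvals,
        "difference_rank": rank,
        "test": test,
    }).set_index("residue")


def positional_matrix(
    dataset: Dataset,
    terminus: str = "N",
    n: int = 15,
    label: Optional[str] = None,
) -> dict[str, pd.DataFrame]:
    """Per-position residue-frequency matrices (n positions x 20 residues).

    N-terminal matrices align sequences from the start, C-terminal from the
    end; a sequence shorter than ``n`` contributes only to the positions it
    reaches, and each occupied position's frequencies sum to 1 over its
    effective sequence count.  Returns one matrix per class label (or one
    entry for ``label`` if given).
    """
    if terminus not in ("N", "C"):
        raise ImportanceError("terminus must be 'N' or 'C'")
    labels = [label] if label else [lab for lab in (POSITIVE, NEGATIVE)
                                    if any(p.label == lab for p in dataset)]
    if not labels:
        labels = [None]  # unlabeled dataset: one pooled matrix keyed "all"
    out: dict[str, pd.DataFrame] = {}
    for lab in labels:
        seqs = [p.sequence for p in dataset if lab is None or p.label == lab]
        counts = np.zeros((n, 20))
        support = np.zeros(n)
        for s in seqs:
            window = s[:n] if terminus == "N" else s[-n:]
            if terminus == "N":
                positions = range(len(window))
            else:
                positions = range(n - len(window), n)
            for pos, c in zip(positions, window):
                counts[pos, AMINO_ACIDS.index(c)] += 1
                support[pos] += 1
        with np.errstate(invalid="ignore"):
            freq = np.where(support[:, None] > 0, counts / np.maximum(support, 1)[:, None], 0.0)
        df = pd.DataFrame(freq, columns=list(AMINO_ACIDS),
                          index=pd.RangeIndex(1, n + 1, name="position"))
        df["n_sequences"] = support.astype(int)
        out[lab or "all"] = df
    return out


def dpc_importance_matrix(report: ImportanceReport) -> pd.DataFrame:
    """Reshape a dipeptide ImportanceReport into a 20x20 MDGI matrix
    (rows = first residue, columns = second)."""
    mat = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    for name, row in report.table.iterrows():
        key = name.split(":")[-1]
        if len(key) == 2 and key[0] in mat.index and key[1] in mat.columns:
            mat.loc[key[0], key[1]] = row["mdgi"]
    return mat
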