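"""Sequence-derived feature encoders for short peptides.

Five schemes, all fixed-dimensional so a forest can consume them directly:

``AAC``
    amino-acid composition: 20 residue frequencies.
``DPC``
    dipeptide composition: 400 overlapping-pair frequencies.
``PCP``
    physicochemical properties: one sequence-averaged value per AAindex
    entry in the supplied property table.
``PseAAC``
    Chou's pseudo amino acid composition: the 20 frequencies augmented
    with lambda sequence-order correlation factors theta_k built from
    squared differences of three standardized residue scales
    (hydrophobicity, hydrophilicity, side-chain mass), jointly normalized
    with weight w so that all 20+lambda components sum to 1.
``Am-PseAAC``
    the amphiphilic variant: 2*lambda interleaved correlation factors
    tau_{2k-1}, tau_{2k} built from hydrophobicity and hydrophilicity
    correlation *products* respectively (dimension 20+2*lambda).

Feature order is frozen: residues alphabetical, dipeptides lexicographic,
properties in table order, correlation factors by tier.  Persisted models
depend on this.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, DIPEPTIDE_INDEX, DIPEPTIDES
from .seqio import Dataset, Peptide, POSITIVE

logger = logging.getLogger(__name__)

# Chou's three canonical PseAAC scales (hydrophobicity = Eisenberg consensus,
# hydrophilicity = Hopp-Woods, side-chain mass in Da), keyed by residue.
HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def standardize_scale(scale: Mapping[str, float]) -> dict[str, float]:
    """Zero-mean / unit-SD standardization over the 20 residues.

    The population SD (ddof=0) is used, following the original pseudo
    amino acid composition convention.
    """
    vals = np.array([scale[aa] for aa in AMINO_ACIDS], dtype=float)
    mu = vals.mean()
    sd = vals.std(ddof=0)
    return {aa: (scale[aa] - mu) / sd for aa in AMINO_ACIDS}


_STD_SCALES: Optional[tuple[dict, dict, dict]] = None


def standardized_pse_scales() -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """The three standardized scales (H1 hydrophobicity, H2 hydrophilicity, M mass)."""
    global _STD_SCALES
    if _STD_SCALES is None:
        _STD_SCALES = (
            standardize_scale(HYDROPHOBICITY),
            standardize_scale(HYDROPHILICITY),
            standardize_scale(SIDE_CHAIN_MASS),
        )
    return _STD_SCALES


class EncodingError(ValueError):
    """A peptide cannot be encoded under the requested scheme/parameters."""


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered numeric encoding of one peptide under one scheme."""

    peptide_id: str
    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.size:
            raise EncodingError(
                f"{self.scheme}: {len(self.names)} names vs {values.size} values")
        if not np.all(np.isfinite(values)):
            raise EncodingError(f"{self.scheme}: non-finite component for "
                                f"peptide {self.peptide_id!r}")

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.peptide_id)


@dataclass(frozen=True)
class PseParams:
    """Pseudo-composition parameters: correlation depth lambda, weight w >= 0."""

    lam: int = 1
    weight: float = 0.05

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


#: Published parameter presets: (PseAAC params, Am-PseAAC params) per dataset
#: style.  "benchmark" is full-length peptides; "nt15" is first-15-residue
#: truncated peptides.
PSE_PRESETS: dict[str, dict[str, PseParams]] = {
    "benchmark": {"pseaac": PseParams(lam=1, weight=0.9),
                  "ampseaac": PseParams(lam=1, weight=0.9)},
    "nt15": {"pseaac": PseParams(lam=2, weight=0.1),
             "ampseaac": PseParams(lam=3, weight=0.2)},
}


# ---------------------------------------------------------------------------
# AAindex property tables
# ---------------------------------------------------------------------------

_AAINDEX_ROW1 = "ARNDCQEGHI"  # residue order of the two I-record value rows
_AAINDEX_ROW2 = "LKMFPSTWYV"


@dataclass
class PropertyTable:
    """A set of AAindex entries: accession -> 20 finite residue values."""

    entries: dict[str, dict[str, float]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for acc, row in self.entries.items():
            missing = [aa for aa in AMINO_ACIDS if aa not in row]
            if missing:
                raise ValueError(f"{acc}: missing residues {missing}")
            if not all(math.isfinite(row[aa]) for aa in AMINO_ACIDS):
                raise ValueError(f"{acc}: non-finite property value")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def accessions(self) -> list[str]:
        return list(self.entries)

    def subset(self, accessions: Iterable[str]) -> "PropertyTable":
        accs = list(accessions)
        unknown = [a for a in accs if a not in self.entries]
        if unknown:
            raise KeyError(f"unknown accession(s): {unknown}")
        return PropertyTable({a: self.entries[a] for a in accs},
                             {a: self.descriptions.get(a, "") for a in accs})

    def standardized(self) -> "PropertyTable":
        return PropertyTable(
            {acc: standardize_scale(row) for acc, row in self.entries.items()},
            dict(self.descriptions),
        )

    @classmethod
    def from_aaindex(cls, path: str | Path) -> "PropertyTable":
        """Parse an AAindex1 flat file (H/D/.../I records, // terminated).

        Entries containing ``NA`` values are dropped with a log message,
        mirroring the usual "properties without NA values" selection.
        """
        entries: dict[str, dict[str, float]] = {}
        descriptions: dict[str, str] = {}
        acc: Optional[str] = None
        desc = ""
        value_rows: list[str] = []
        in_values = False
        dropped = 0

        def flush():
            nonlocal acc, desc, value_rows, in_values, dropped
            if acc is not None and value_rows:
                tokens = " ".join(value_rows).split()
                if len(tokens) != 20:
                    raise ValueError(f"{acc}: expected 20 values, got {len(tokens)}")
                if any(t.upper() == "NA" for t in tokens):
                    dropped += 1
                else:
                    order = _AAINDEX_ROW1 + _AAINDEX_ROW2
                    entries[acc] = {aa: float(t) for aa, t in zip(order, tokens)}
                    descriptions[acc] = desc
            acc, desc, value_rows, in_values = None, "", [], False

        with open(path) as fh:
            for line in fh:
                if line.startswith("//"):
                    flush()
                elif line.startswith("H "):
                    acc = line[2:].strip()
                elif line.startswith("D "):
                    desc = line[2:].strip()
                elif line.startswith("I "):
                    in_values = True
                elif in_values and line.startswith(" "):
                    value_rows.append(line)
                elif line[:1].isalpha():
                    in_values = False
        flush()
        if dropped:
            logger.info("from_aaindex: dropped %d entrie(s) containing NA", dropped)
        return cls(entries, descriptions)

    @classmethod
    def bundled(cls) -> "PropertyTable":
        """The property table shipped with the package (a small AAindex subset)."""
        ref = resources.files("antiangio").joinpath("data/aaindex_subset.txt")
        with resources.as_file(ref) as path:
            return cls.from_aaindex(path)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def _counts(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for c in sequence:
        try:
            counts[AA_INDEX[c]] += 1
        except KeyError:
            raise EncodingError(f"non-standard residue {c!r} in sequence")
    return counts


def encode_aac(p: Peptide) -> FeatureVector:
    """Amino-acid composition: 20 occurrence frequencies summing to 1."""
    freqs = _counts(p.sequence) / len(p.sequence)
    return FeatureVector(p.id, "AAC", tuple(AMINO_ACIDS), freqs)


def encode_dpc(p: Peptide) -> FeatureVector:
    """Dipeptide composition: 400 overlapping-pair frequencies over L-1 windows."""
    L = len(p.sequence)
    if L < 2:
        raise EncodingError(f"peptide {p.id!r}: sequence too short for DPC (L={L})")
    counts = np.zeros(400)
    for i in range(L - 1):
        try:
            counts[DIPEPTIDE_INDEX[p.sequence[i:i + 2]]] += 1
        except KeyError:
            raise EncodingError(f"non-standard residue in {p.sequence[i:i + 2]!r}")
    return FeatureVector(p.id, "DPC", DIPEPTIDES, counts / (L - 1))


def encode_pcp(p: Peptide, table: PropertyTable, standardize: bool = True) -> FeatureVector:
    """Sequence-averaged physicochemical properties, one component per entry.

    With ``standardize`` each 20-value scale is z-scored over the alphabet
    before averaging, so properties on wildly different units (mass vs
    hydropathy) contribute comparably.
    """
    use = table.standardized() if standardize else table
    values = []
    for acc in use.accessions:
        row = use.entries[acc]
        try:
            values.append(sum(row[c] for c in p.sequence) / len(p.sequence))
        except KeyError as exc:
            raise EncodingError(f"{acc}: no value for residue {exc.args[0]!r}")
    return FeatureVector(p.id, "PCP", tuple(use.accessions), np.array(values))


def pse_correlation(p: Peptide, k: int) -> float:
    """k-tier sequence-order correlation factor theta_k.

    theta_k = (1/(L-k)) * sum_i Theta(R_i, R_{i+k}) where Theta is the mean
    squared difference of the two residues over the three standardized
    scales.  Symmetric in its arguments, hence invariant under sequence
    reversal; identically zero on homopolymers.
    """
    L = len(p.sequence)
    if not (1 <= k < L):
        raise EncodingError(f"peptide {p.id!r}: correlation tier k={k} needs 1 <= k < L={L}")
    h1, h2, m = standardized_pse_scales()
    total = 0.0
    for i in range(L - k):
        a, b = p.sequence[i], p.sequence[i + k]
        total += ((h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2) / 3.0
    return total / (L - k)


def encode_pseaac(p: Peptide, params: PseParams) -> FeatureVector:
    """Pseudo amino acid composition: 20 + lambda components summing to 1.

    p_u = f_u / (1 + w * sum theta)          for u <= 20
    p_{20+k} = w * theta_k / (1 + w * sum theta)

    with f the residue frequencies (which sum to 1 by construction, hence
    the unit term).  lambda=0 or w=0 degenerate to AAC exactly.
    """
    L = len(p.sequence)
    if L <= params.lam:
        raise EncodingError(f"peptide {p.id!r}: lambda={params.lam} too large "
                            f"for sequence of length {L}")
    freqs = _counts(p.sequence) / L
    thetas = np.array([pse_correlation(p, k) for k in range(1, params.lam + 1)])
    denom = 1.0 + params.weight * thetas.sum()
    values = np.concatenate([freqs / denom, params.weight * thetas / denom])
    names = tuple(AMINO_ACIDS) + tuple(f"theta{k}" for k in range(1, params.lam + 1))
    return FeatureVector(p.id, "PseAAC", names, values)


def _amphiphilic_taus(p: Peptide, lam: int) -> np.ndarray:
    """Interleaved hydrophobicity/hydrophilicity correlation products.

    tau_{2k-1} = (1/(L-k)) * sum_i H1(R_i) * H1(R_{i+k})
    tau_{2k}   = (1/(L-k)) * sum_i H2(R_i) * H2(R_{i+k})
    """
    L = len(p.sequence)
    h1, h2, _ = standardized_pse_scales()
    taus = []
    for k in range(1, lam + 1):
        t1 = sum(h1[p.sequence[i]] * h1[p.sequence[i + k]] for i in range(L - k)) / (L - k)
        t2 = sum(h2[p.sequence[i]] * h2[p.sequence[i + k]] for i in range(L - k)) / (L - k)
        taus.extend([t1, t2])
    return np.array(taus)


def encode_ampseaac(p: Peptide, params: PseParams) -> FeatureVector:
    """Amphiphilic pseudo amino acid composition: 20 + 2*lambda components.

    The 2*lambda sequence-order factors track hydrophobicity and
    hydrophilicity correlations separately (interleaved per tier); the
    joint normalization makes all components sum to 1.

    Unlike the squared-difference factors of PseAAC, the correlation
    products here are signed, so for short strongly amphiphilic sequences
    the normalizer 1 + w * sum(tau) can be negative and individual
    components can leave [0, 1]; the unit component sum still holds for
    any non-vanishing normalizer.  Keeping the weight small (the presets
    use 0.2-0.9) makes this rare in practice.
    """
    L = len(p.sequence)
    if L <= params.lam:
        raise EncodingError(f"peptide {p.id!r}: lambda={params.lam} too large "
                            f"for sequence of length {L}")
    freqs = _counts(p.sequence) / L
    taus = _amphiphilic_taus(p, params.lam)
    denom = 1.0 + params.weight * taus.sum()
    if abs(denom) < 1e-12:
        raise EncodingError(f"peptide {p.id!r}: vanishing Am-PseAAC normalizer")
    values = np.concatenate([freqs / denom, params.weight * taus / denom])
    names = tuple(AMINO_ACIDS) + tuple(
        f"tau{2 * k - 1 + j}" for k in range(1, params.lam + 1) for j in (0, 1))
    return FeatureVector(p.id, "Am-PseAAC", names, values)


def concat(vectors: Sequence[FeatureVector], dedupe_aac: bool = False) -> FeatureVector:
    """Concatenate encodings of the same peptide with scheme-prefixed names.

    With ``dedupe_aac`` repeated pure-AAC blocks beyond the first are
    dropped (the pseudo-composition leading blocks are rescaled AAC, not
    identical, and are always kept).  The resulting dimension is logged.
    """
    if not vectors:
        raise EncodingError("concat: empty input")
    pid = vectors[0].peptide_id
    for v in vectors[1:]:
        if v.peptide_id != pid:
            raise EncodingError(f"concat: peptide id mismatch "
                                f"({pid!r} vs {v.peptide_id!r})")
    if len(vectors) == 1:
        return vectors[0]
    kept: list[FeatureVector] = []
    seen_aac = False
    for v in vectors:
        if dedupe_aac and v.scheme == "AAC":
            if seen_aac:
                continue
            seen_aac = True
        kept.append(v)
    names = tuple(f"{v.scheme}:{n}" for v in kept for n in v.names)
    values = np.concatenate([v.values for v in kept])
    scheme = "+".join(v.scheme for v in kept)
    logger.debug("concat %s -> %d components", scheme, values.size)
    return FeatureVector(pid, scheme, names, values)


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------

#: The nine feature combinations of the evaluation protocol.
FEATURE_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "AAC": ("AAC",),
    "DPC": ("DPC",),
    "PCP": ("PCP",),
    "PseAAC": ("PseAAC",),
    "Am-PseAAC": ("Am-PseAAC",),
    "AAC+PseAAC": ("AAC", "PseAAC"),
    "AAC+Am-PseAAC": ("AAC", "Am-PseAAC"),
    "PseAAC+Am-PseAAC": ("PseAAC", "Am-PseAAC"),
    "AAC+PseAAC+Am-PseAAC": ("AAC", "PseAAC", "Am-PseAAC"),
}


def encode_peptide(
    p: Peptide,
    schemes: Sequence[str],
    pse_params: PseParams = PseParams(),
    am_params: Optional[PseParams] = None,
    table: Optional[PropertyTable] = None,
    standardize: bool = True,
    dedupe_aac: bool = False,
) -> FeatureVector:
    """Encode one peptide under a scheme list, concatenating as needed."""
    am_params = am_params or pse_params
    vectors = []
    for scheme in schemes:
        if scheme == "AAC":
            vectors.append(encode_aac(p))
        elif scheme == "DPC":
            vectors.append(encode_dpc(p))
        elif scheme == "PCP":
            vectors.append(encode_pcp(p, table or PropertyTable.bundled(),
                                      standardize=standardize))
        elif scheme == "PseAAC":
            vectors.append(encode_pseaac(p, pse_params))
        elif scheme == "Am-PseAAC":
            vectors.append(encode_ampseaac(p, am_params))
        else:
            raise EncodingError(
                f"unknown scheme {scheme!r}; valid: AAC, DPC, PCP, PseAAC, Am-PseAAC")
    return concat(vectors, dedupe_aac=dedupe_aac)


def feature_matrix(
    dataset: Dataset,
    combination: str | Sequence[str],
    pse_params: PseParams = PseParams(),
    am_params: Optional[PseParams] = None,
    table: Optional[PropertyTable] = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, Optional[pd.Series]]:
    """Encode a whole dataset.

    ``combination`` is either a registered name from
    :data:`FEATURE_COMBINATIONS` or an explicit scheme sequence.  Returns
    the feature matrix (rows = peptide ids) and, when the dataset is
    labeled, a 0/1 series (1 = positive / anti-angiogenic).
    """
    if isinstance(combination, str):
        try:
            schemes = FEATURE_COMBINATIONS[combination]
        except KeyError:
            raise EncodingError(
                f"unknown feature combination {combination!r}; valid: "
                f"{', '.join(FEATURE_COMBINATIONS)}")
    else:
        schemes = tuple(combination)
    if "PCP" in schemes and table is None:
        table = PropertyTable.bundled()
    rows = [encode_peptide(p, schemes, pse_params, am_params, table, standardize)
            for p in dataset]
    X = pd.DataFrame([r.values for r in rows],
                     index=[r.peptide_id for r in rows],
                     columns=list(rows[0].names) if rows else [])
    labels = None
    if rows and all(p.label is not None for p in dataset):
        labels = pd.Series([1 if p.label == POSITIVE else 0 for p in dataset],
                           index=X.index, name="label")
    logger.debug("feature_matrix %s: %d peptides x %d features",
                 "+".join(schemes), X.shape[0], X.shape[1])
    return X, labels


def optimize_pse_params(
    dataset: Dataset,
    scheme: str = "PseAAC",
    weights: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1)),
    lambdas: Sequence[int] = tuple(range(1, 11)),
    folds: int = 5,
    seed: int = 0,
    rf_config=None,
) -> tuple[PseParams, pd.DataFrame]:
    """Grid-search lambda and weight by k-fold CV accuracy of the forest.

    Grid points with lambda >= the shortest sequence are skipped with a
    warning.  Ties prefer smaller lambda, then smaller weight.  Returns the
    winning parameters and the full grid trace.
    """
    from .evaluate import kfold_cv_matrix
    from .model import RFConfig

    if scheme not in ("PseAAC", "Am-PseAAC"):
        raise EncodingError("optimize_pse_params applies to PseAAC / Am-PseAAC")
    dataset.require_labels()
    rf_config = rf_config or RFConfig(seed=seed)
    min_len = min(len(p) for p in dataset)
    records = []
    for lam in lambdas:
        if lam >= min_len:
            logger.warning("skipping lambda=%d (shortest sequence has length %d)",
                           lam, min_len)
            continue
        for w in weights:
            params = PseParams(lam=lam, weight=float(w))
            X, y = feature_matrix(dataset, (scheme,), pse_params=params,
                                  am_params=params)
            result = kfold_cv_matrix(X, y, rf_config, k=folds, seed=seed)
            records.append({"lambda": lam, "weight": float(w), "cv_accuracy": result.ac})
    if not records:
        raise EncodingError("no feasible grid points (sequences too short)")
    trace = pd.DataFrame(records)
    best = trace.sort_values(["cv_accuracy", "lambda", "weight"],
                             ascending=[False, True, True]).iloc[0]
    logger.info("optimize_pse_params %s: best lambda=%d weight=%.1f (CV acc %.4f)",
                scheme, int(best["lambda"]), best["weight"], best["cv_accuracy"])
    return PseParams(lam=int(best["lambda"]), weight=float(best["weight"])), trace
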