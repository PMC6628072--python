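"""Reading, validating, filtering, truncating and splitting peptide datasets.

A dataset is an ordered collection of :class:`Peptide` records with unique
ids and optional binary activity labels (``positive`` = anti-angiogenic,
``negative`` = non-antiangiogenic).  The operations here mirror the standard
benchmark-construction recipe for short bioactive peptides: drop sequences
with non-standard residues (X, U, B, Z, ...), collapse near-duplicates with
a greedy identity filter, optionally keep only the first N residues of the
N-terminus, and draw stratified repeated train/test splits.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO as _BioSeqIO

from .alphabet import is_standard, nonstandard_residues

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(ValueError):
    """A peptide record violates the sequence or id invariants."""


@dataclass(frozen=True)
class Peptide:
    """One peptide record: identifier, upper-case sequence, optional label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("peptide id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"peptide {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"peptide {self.id!r}: label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def is_standard(self) -> bool:
        return is_standard(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """Ordered peptide collection with unique ids."""

    peptides: list[Peptide] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self):
        ids = [p.id for p in self.peptides]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate peptide ids: {dupes}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, peptide_id: str) -> Peptide:
        for p in self.peptides:
            if p.id == peptide_id:
                return p
        raise KeyError(peptide_id)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def labels(self) -> list[Optional[str]]:
        return [p.label for p in self.peptides]

    def subset(self, ids: Iterable[str], name: Optional[str] = None) -> "Dataset":
        wanted = set(ids)
        return Dataset(
            [p for p in self.peptides if p.id in wanted],
            name=name or self.name,
        )

    def by_label(self, label: str) -> "Dataset":
        return Dataset([p for p in self.peptides if p.label == label],
                       name=f"{self.name}:{label}")

    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for p in self.peptides:
            if p.label is not None:
                counts[p.label] += 1
        return counts

    def require_labels(self) -> None:
        """For training use: every peptide labeled, both classes non-empty."""
        if any(p.label is None for p in self.peptides):
            raise ValidationError(f"dataset {self.name!r} contains unlabeled peptides")
        counts = self.class_counts()
        empty = [lab for lab, n in counts.items() if n == 0]
        if empty:
            raise ValidationError(f"dataset {self.name!r}: empty class(es) {empty}")


def _validate_standard(p: Peptide) -> None:
    bad = nonstandard_residues(p.sequence)
    if bad:
        raise ValidationError(
            f"peptide {p.id!r}: non-standard residue(s) {', '.join(repr(c) for c in bad)}"
        )


def read_fasta(
    path: str | Path,
    label: Optional[str] = None,
    name: Optional[str] = None,
    strict: bool = True,
) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    The id is the header token before the first whitespace.  With
    ``strict=True`` (default) any sequence containing a character outside
    the 20-letter alphabet raises :class:`ValidationError` naming the
    offending character; pass ``strict=False`` to load such records for a
    subsequent :func:`clean`.
    """
    path = Path(path)
    # Biopython tolerates leading junk silently; detect it up front so the
    # error carries a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError("expected '>' header before sequence data",
                                      line=lineno)
            break

    peptides: list[Peptide] = []
    with open(path) as fh:
        for record in _BioSeqIO.parse(fh, "fasta"):
            if not record.id:
                raise FastaParseError(f"record with empty id in {path}")
            p = Peptide(id=record.id, sequence=str(record.seq), label=label)
            if strict:
                _validate_standard(p)
            peptides.append(p)
    if not peptides:
        logger.warning("FASTA file %s contained no records", path)
    return Dataset(peptides, name=name or path.stem)


def write_fasta(dataset: Dataset, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in dataset:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


def read_manifest(path: str | Path, name: Optional[str] = None) -> Dataset:
    """Read a CSV manifest with columns ``id,sequence,label`` (label optional)."""
    path = Path(path)
    peptides: list[Peptide] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames \
                or "sequence" not in reader.fieldnames:
            raise ValidationError(f"{path}: manifest needs 'id' and 'sequence' columns")
        for row in reader:
            label = row.get("label") or None
            peptides.append(Peptide(id=row["id"], sequence=row["sequence"], label=label))
    return Dataset(peptides, name=name or path.stem)


def write_manifest(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "label"])
        for p in dataset:
            writer.writerow([p.id, p.sequence, p.label or ""])


def clean(dataset: Dataset, drop_nonstandard: bool = True) -> Dataset:
    """Remove peptides containing residues outside the 20-letter alphabet.

    With ``drop_nonstandard=False`` the first offending peptide raises
    instead.  Idempotent.
    """
    kept: list[Peptide] = []
    dropped = 0
    for p in dataset:
        if p.is_standard:
            kept.append(p)
        elif drop_nonstandard:
            dropped += 1
        else:
            _validate_standard(p)
    if dropped:
        logger.info("clean: removed %d/%d peptides with non-standard residues",
                    dropped, len(dataset))
    if not kept:
        logger.warning("clean: dataset %r is empty after filtering", dataset.name)
    return Dataset(kept, name=dataset.name)


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped identity: matching positions over the shorter length."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / n


def redundancy_filter(dataset: Dataset, identity_threshold: float = 0.90) -> Dataset:
    """Greedy longest-first redundancy reduction.

    Sequences are visited longest first (ties keep input order); a sequence
    is discarded iff its ungapped identity with an already-kept
    representative is strictly greater than ``identity_threshold``.
    Deterministic and seed-free; the output preserves input order.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(range(len(dataset.peptides)),
                   key=lambda i: (-len(dataset.peptides[i]), i))
    kept_idx: list[int] = []
    for i in order:
        seq = dataset.peptides[i].sequence
        if all(pairwise_identity(seq, dataset.peptides[j].sequence) <= identity_threshold
               for j in kept_idx):
            kept_idx.append(i)
    removed = len(dataset) - len(kept_idx)
    if removed:
        logger.info("redundancy_filter: removed %d/%d peptides at threshold %.2f",
                    removed, len(dataset), identity_threshold)
    kept_idx.sort()
    return Dataset([dataset.peptides[i] for i in kept_idx], name=dataset.name)


def truncate_nt(dataset: Dataset, n: int = 15) -> Dataset:
    """Keep the first ``min(n, L)`` N-terminal residues of every peptide."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Dataset(
        [replace(p, sequence=p.sequence[:n]) for p in dataset],
        name=f"{dataset.name}-NT{n}" if not dataset.name.endswith(f"-NT{n}")
        else dataset.name,
    )


@dataclass(frozen=True)
class SplitPlan:
    """One train/test partition of a labeled dataset."""

    round_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(f"split round {self.round_index}: ids in both "
                                  f"train and test: {sorted(overlap)[:5]}")

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }


def save_splits(plans: Sequence[SplitPlan], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in plans], fh, indent=1)


def load_splits(path: str | Path) -> list[SplitPlan]:
    with open(path) as fh:
        raw = json.load(fh)
    return [SplitPlan(round_index=d["round_index"],
                      train_ids=tuple(d["train_ids"]),
                      test_ids=tuple(d["test_ids"]),
                      train_fraction=d["train_fraction"],
                      seed=d["seed"]) for d in raw]


def derive_round_seed(master_seed: int, round_index: int) -> int:
    """Per-round seed: a fixed affine hash of (master seed, round index).

    The multiplier is an arbitrary large prime; the modulus keeps the value
    a valid 31-bit seed.  Documented so any single round can be regenerated
    in isolation.
    """
    return (master_seed * 1_000_003 + round_index * 7919) % (2 ** 31)


def make_splits(
    dataset: Dataset,
    rounds: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> list[SplitPlan]:
    """Stratified repeated random train/test splits.

    Each round shuffles every class independently with its own derived seed
    and puts ``floor(train_fraction * n_class)`` members in the training
    set; the residual goes to the test set.  Same master seed, same plans.
    """
    import numpy as np

    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    dataset.require_labels()
    for lab, n in dataset.class_counts().items():
        if n < 2:
            raise ValidationError(f"class {lab!r} has {n} member(s); need >= 2 to split")

    by_class = {lab: [p.id for p in dataset if p.label == lab] for lab in LABELS}
    plans: list[SplitPlan] = []
    for r in range(1, rounds + 1):
        round_seed = derive_round_seed(seed, r)
        rng = np.random.default_rng(round_seed)
        train: list[str] = []
        test: list[str] = []
        for lab in LABELS:
            ids = list(by_class[lab])
            rng.shuffle(ids)
            n_train = int(np.floor(train_fraction * len(ids)))
            # never allow an empty side within a class
            n_train = min(max(n_train, 1), len(ids) - 1)
            train.extend(ids[:n_train])
            test.extend(ids[n_train:])
        plans.append(SplitPlan(round_index=r,
                               train_ids=tuple(train),
                               test_ids=tuple(test),
                               train_fraction=train_fraction,
                               seed=round_seed))
    return plans
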