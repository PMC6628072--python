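"""Synthetic labeled peptide datasets with controllable class structure.

The generator draws residues i.i.d. from a per-class composition over the
20-letter alphabet, with lengths uniform over a range.  The default
compositions are the published class-mean amino-acid compositions of
anti-angiogenic versus non-antiangiogenic peptides (renormalized to exact
simplexes), so the default output mimics the composition-level signal of
the real benchmark: Cys, Ser and Arg enriched in the positive class, Leu,
Ala and Val in the negative class.  No positional or order structure is
generated; downstream order-sensitive encodings therefore carry no extra
class signal beyond composition.

``plant_signal`` shifts a single residue's probability by +delta in the
positive class and -delta in the negative class (renormalizing the other
residues proportionally), giving datasets with one known discriminative
feature for importance-recovery experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .alphabet import AMINO_ACIDS
from .seqio import Dataset, NEGATIVE, POSITIVE, Peptide, write_fasta, write_manifest

logger = logging.getLogger(__name__)

# Class-mean amino-acid compositions of the anti-angiogenic (positive) and
# non-antiangiogenic (negative) benchmark classes; fractions, renormalized
# at use (printed values carry rounding error of ~2e-3 in the totals).
ANGIO_COMPOSITION: dict[str, float] = {
    "A": 0.053, "C": 0.047, "D": 0.047, "E": 0.046, "F": 0.030,
    "G": 0.081, "H": 0.030, "I": 0.046, "K": 0.056, "L": 0.067,
    "M": 0.019, "N": 0.037, "P": 0.060, "Q": 0.039, "R": 0.088,
    "S": 0.096, "T": 0.062, "V": 0.048, "W": 0.023, "Y": 0.023,
}
NON_ANGIO_COMPOSITION: dict[str, float] = {
    "A": 0.086, "C": 0.014, "D": 0.052, "E": 0.065, "F": 0.043,
    "G": 0.073, "H": 0.024, "I": 0.064, "K": 0.056, "L": 0.095,
    "M": 0.023, "N": 0.040, "P": 0.045, "Q": 0.042, "R": 0.055,
    "S": 0.057, "T": 0.054, "V": 0.073, "W": 0.012, "Y": 0.029,
}


def _as_simplex(composition: Mapping[str, float]) -> np.ndarray:
    vec = np.array([composition.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if vec.min() < 0:
        raise ValueError("composition probabilities must be non-negative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("composition must have positive mass")
    return vec / total


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the benchmark conditions: 137 peptides per class, lengths
    uniform on [5, 50], class compositions as published.
    """

    n_pos: int = 137
    n_neg: int = 137
    length_range: tuple[int, int] = (5, 50)
    pos_composition: tuple[float, ...] = field(
        default_factory=lambda: tuple(_as_simplex(ANGIO_COMPOSITION)))
    neg_composition: tuple[float, ...] = field(
        default_factory=lambda: tuple(_as_simplex(NON_ANGIO_COMPOSITION)))
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        for name in ("pos_composition", "neg_composition"):
            vec = np.asarray(getattr(self, name))
            if vec.size != 20 or vec.min() < 0 or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 20-simplex")


def generate(spec: GeneratorSpec) -> Dataset:
    """Draw a labeled dataset; identical spec (incl. seed) -> identical bytes."""
    rng = np.random.default_rng(spec.seed)
    residues = np.array(list(AMINO_ACIDS))
    lo, hi = spec.length_range
    peptides: list[Peptide] = []
    for label, n, comp, prefix in (
        (POSITIVE, spec.n_pos, spec.pos_composition, "pos"),
        (NEGATIVE, spec.n_neg, spec.neg_composition, "neg"),
    ):
        probs = np.asarray(comp)
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(residues, size=length, p=probs))
            peptides.append(Peptide(id=f"{prefix}_{i + 1:04d}", sequence=seq,
                                    label=label))
    return Dataset(peptides, name=f"synthetic-seed{spec.seed}")


def plant_signal(spec: GeneratorSpec, residue: str, delta: float) -> GeneratorSpec:
    """Shift one residue's probability by +delta (positives) / -delta (negatives).

    The remaining residues are renormalized proportionally in each class.
    Raises if either shifted composition leaves the simplex; the boundary
    cases (probability exactly 0 or 1) are allowed.
    """
    if residue not in AMINO_ACIDS:
        raise ValueError(f"unknown residue {residue!r}")
    j = AMINO_ACIDS.index(residue)

    def shift(comp: tuple[float, ...], d: float) -> tuple[float, ...]:
        vec = np.asarray(comp, dtype=float)
        target = vec[j] + d
        if not (0.0 <= target <= 1.0):
            raise ValueError(
                f"delta={delta} infeasible: p({residue}) would become {target:.3f}")
        rest = vec.sum() - vec[j]
        out = np.empty_like(vec)
        if rest > 0:
            out[:] = vec * (1.0 - target) / rest
        else:
            if target < 1.0:
                raise ValueError(f"delta={delta} infeasible: no other residue "
                                 "has mass to renormalize")
            out[:] = 0.0
        out[j] = target
        return tuple(out)

    return replace(spec,
                   pos_composition=shift(spec.pos_composition, +delta),
                   neg_composition=shift(spec.neg_composition, -delta))


def emit_files(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write positive/negative FASTA files plus a CSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "positive_fasta": outdir / "positive.fasta",
        "negative_fasta": outdir / "negative.fasta",
        "manifest": outdir / "manifest.csv",
    }
    write_fasta(Dataset([p for p in dataset if p.label == POSITIVE], name="pos"),
                paths["positive_fasta"])
    write_fasta(Dataset([p for p in dataset if p.label == NEGATIVE], name="neg"),
                paths["negative_fasta"])
    write_manifest(dataset, paths["manifest"])
    logger.info("emit_files: wrote %d peptides to %s", len(dataset), outdir)
    return paths
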