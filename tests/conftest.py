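import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from antiangio import Dataset, GeneratorSpec, Peptide, generate
from antiangio.seqio import NEGATIVE, POSITIVE


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture
def toy_separable():
    """Cys-rich positives vs Leu-rich negatives: linearly separable in AAC."""
    rng = np.random.default_rng(7)
    peptides = []
    for i in range(20):
        seq = "".join(rng.choice(list("CCCCGS"), size=12))
        peptides.append(Peptide(f"pos{i}", seq, POSITIVE))
    for i in range(20):
        seq = "".join(rng.choice(list("LLLLAV"), size=12))
        peptides.append(Peptide(f"neg{i}", seq, NEGATIVE))
    return Dataset(peptides, name="toy")


@pytest.fixture
def benchmark_like():
    """Default generator conditions: 137 + 137, published class compositions."""
    return generate(GeneratorSpec(seed=11))


@pytest.fixture
def small_labeled():
    """Small composition-shifted dataset for fast model/CV tests."""
    return generate(GeneratorSpec(n_pos=40, n_neg=40, length_range=(8, 25), seed=3))
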