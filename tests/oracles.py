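"""Independent brute-force oracles for cross-checking the encoders and AUC.

Deliberately naive: explicit Python loops, no shared helper code with the
package beyond the raw (unstandardized) scale constants, which are inputs
to the method rather than part of its algorithm.
"""

import math

from scipy.stats import rankdata

from antiangio.features import HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _standardize(raw: dict) -> dict:
    vals = [raw[a] for a in ALPHABET]
    mean = sum(vals) / 20.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
    return {a: (raw[a] - mean) / sd for a in ALPHABET}


def theta_oracle(seq: str, k: int) -> float:
    """k-tier correlation factor by direct substitution."""
    h1 = _standardize(HYDROPHOBICITY)
    h2 = _standardize(HYDROPHILICITY)
    m = _standardize(SIDE_CHAIN_MASS)
    total = 0.0
    for i in range(len(seq) - k):
        a, b = seq[i], seq[i + k]
        d1 = h1[b] - h1[a]
        d2 = h2[b] - h2[a]
        d3 = m[b] - m[a]
        total += (d1 * d1 + d2 * d2 + d3 * d3) / 3.0
    return total / (len(seq) - k)


def pseaac_oracle(seq: str, lam: int, weight: float) -> list:
    """Pseudo amino acid composition by naive double loop."""
    freqs = [seq.count(a) / len(seq) for a in ALPHABET]
    thetas = [theta_oracle(seq, k) for k in range(1, lam + 1)]
    denom = 1.0 + weight * sum(thetas)
    return [f / denom for f in freqs] + [weight * t / denom for t in thetas]


def ampseaac_oracle(seq: str, lam: int, weight: float) -> list:
    """Amphiphilic pseudo amino acid composition by naive double loop."""
    h1 = _standardize(HYDROPHOBICITY)
    h2 = _standardize(HYDROPHILICITY)
    freqs = [seq.count(a) / len(seq) for a in ALPHABET]
    taus = []
    for k in range(1, lam + 1):
        t1 = sum(h1[seq[i]] * h1[seq[i + k]] for i in range(len(seq) - k)) / (len(seq) - k)
        t2 = sum(h2[seq[i]] * h2[seq[i + k]] for i in range(len(seq) - k)) / (len(seq) - k)
        taus.append(t1)
        taus.append(t2)
    denom = 1.0 + weight * sum(taus)
    return [f / denom for f in freqs] + [weight * t / denom for t in taus]


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    labels = [1 if (l == 1 or l == "positive" or l is True) else 0 for l in labels]
    ranks = rankdata(scores)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    rank_sum_pos = sum(r for r, l in zip(ranks, labels) if l == 1)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def random_peptide(rng, min_len=5, max_len=50) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
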