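"""The standard 20-letter amino-acid alphabet and frozen feature orderings.

Feature orderings are part of the persisted-model contract: residues are
alphabetical by one-letter code, dipeptides lexicographic. Changing them
would silently invalidate saved models, so they live here and nowhere else.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

DIPEPTIDE_INDEX: dict[str, int] = {dp: i for i, dp in enumerate(DIPEPTIDES)}

#: Three-letter names, occasionally useful in reports.
THREE_LETTER: dict[str, str] = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}


def is_standard(sequence: str) -> bool:
    """True if every character is one of the 20 standard residues."""
    return bool(sequence) and all(c in AA_INDEX for c in sequence)


def nonstandard_residues(sequence: str) -> list[str]:
    """Ordered, de-duplicated list of characters outside the alphabet."""
    seen: list[str] = []
    for c in sequence:
        if c not in AA_INDEX and c not in seen:
            seen.append(c)
    return seen
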