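"""IUPAC nucleotide ambiguity-code algebra.

Direct Sanger sequencing of a diploid amplicon reads both chromosomes at
once; a position where the two alleles differ shows a double peak that base
callers encode as an IUPAC ambiguity symbol (R = A/G, Y = C/T, ...).  This
module provides the small algebra needed to move between base sets and
symbols: it is the formal counterpart of "the two alleles that, combined,
explain the consensus".
"""

from __future__ import annotations

# Symbol -> set of concrete bases it denotes (the 15 standard symbols).
AMBIGUITY_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_SYMBOL: dict[frozenset[str], str] = {v: k for k, v in AMBIGUITY_SETS.items()}

BASES = "ACGT"
IUPAC_SYMBOLS = frozenset(AMBIGUITY_SETS)


class InvalidBaseError(ValueError):
    """A symbol outside the expected alphabet was supplied."""


def base_set(symbol: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC symbol denotes."""
    try:
        return AMBIGUITY_SETS[symbol]
    except KeyError:
        raise InvalidBaseError(f"not an IUPAC nucleotide symbol: {symbol!r}") from None


def is_ambiguous(symbol: str) -> bool:
    """True for any symbol denoting more than one base (R, Y, ..., N)."""
    return len(base_set(symbol)) > 1


def iupac_union(b1: str, b2: str) -> str:
    """IUPAC symbol for the union of two concrete bases.

    Models the diploid consensus at one position: two identical bases give
    that base back, two different bases give the two-base ambiguity symbol.
    Commutative; inputs must be concrete A/C/G/T.
    """
    if b1 not in AMBIGUITY_SETS or len(AMBIGUITY_SETS[b1]) != 1:
        raise InvalidBaseError(f"expected a concrete base A/C/G/T, got {b1!r}")
    if b2 not in AMBIGUITY_SETS or len(AMBIGUITY_SETS[b2]) != 1:
        raise InvalidBaseError(f"expected a concrete base A/C/G/T, got {b2!r}")
    return SET_TO_SYMBOL[frozenset((b1, b2))]


def union_sequence(s1: str, s2: str) -> str:
    """Position-wise :func:`iupac_union` of two equal-length ACGT sequences."""
    if len(s1) != len(s2):
        raise ValueError(f"sequence lengths differ: {len(s1)} vs {len(s2)}")
    return "".join(iupac_union(a, b) for a, b in zip(s1, s2))
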