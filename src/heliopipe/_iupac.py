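"""Shared IUPAC nucleotide code tables for unphased diploid sequences."""

from __future__ import annotations

#: two-base ambiguity codes for heterozygous diploid genotypes
AMBIGUITY: dict[str, tuple[str, str]] = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

BASES = ("A", "C", "G", "T")

_PAIR_TO_CODE = {frozenset(pair): code for code, pair in AMBIGUITY.items()}

MISSING = "N"

VALID_DIPLOID = set(BASES) | set(AMBIGUITY) | {MISSING}


def alleles(char: str) -> tuple[str, str]:
    """Return the unordered allele pair encoded by a diploid character."""
    if char in AMBIGUITY:
        return AMBIGUITY[char]
    if char in BASES:
        return (char, char)
    raise ValueError(f"not a resolvable diploid character: {char!r}")


def diploid_code(a: str, b: str) -> str:
    """Collapse an unordered base pair to its single-letter diploid code."""
    if a == MISSING or b == MISSING:
        return MISSING
    if a == b:
        if a not in BASES:
            raise ValueError(f"not a nucleotide: {a!r}")
        return a
    try:
        return _PAIR_TO_CODE[frozenset((a, b))]
    except KeyError:
        raise ValueError(f"not a nucleotide pair: {a!r}/{b!r}") from None


def is_het(char: str) -> bool:
    return char in AMBIGUITY
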