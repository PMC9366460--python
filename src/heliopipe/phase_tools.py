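"""Heterozygote phase-resolution utilities.

An unphased diploid sequence with ``h`` heterozygous (two-base IUPAC) sites
admits ``2^h`` ordered assignments of alleles to its two haplotypes, but
only ``max(1, 2^(h-1))`` distinct *unordered* haplotype pairs because
swapping the haplotypes gives the same pair.  This module enumerates those
resolutions exactly, draws one uniformly at random (mimicking the chimaeric
haplotypes produced by naive assembly phasing), and builds single haploid
consensus sequences with one base kept per heterozygous site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._iupac import AMBIGUITY, MISSING, VALID_DIPLOID, is_het


def _validate(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted(set(seq) - VALID_DIPLOID)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")


def het_count(seq: str) -> int:
    """Number of two-base ambiguity characters in the sequence."""
    _validate(seq)
    return sum(1 for c in seq if is_het(c))


def enumerate_phase_resolutions(seq: str) -> list[tuple[str, str]]:
    """All distinct unordered haplotype pairs consistent with ``seq``.

    The first heterozygous site is fixed to a canonical orientation (its
    alphabetically first base on haplotype one), which yields each unordered
    pair exactly once: ``2^(h-1)`` pairs for ``h >= 1`` heterozygous sites,
    one pair for ``h <= 1``.  Missing sites (N) stay N on both haplotypes.
    """
    _validate(seq)
    het_sites = [i for i, c in enumerate(seq) if is_het(c)]
    base1 = list(seq)
    base2 = list(seq)
    resolutions: list[tuple[str, str]] = []
    n_free = max(0, len(het_sites) - 1)
    for bits in range(2 ** n_free):
        h1, h2 = base1[:], base2[:]
        for rank, i in enumerate(het_sites):
            a, b = AMBIGUITY[seq[i]]  # alphabetical order
            if rank == 0:
                flip = 0  # canonical orientation at the first het site
            else:
                flip = (bits >> (rank - 1)) & 1
            h1[i], h2[i] = (a, b) if not flip else (b, a)
        resolutions.append(("".join(h1), "".join(h2)))
    return resolutions


def random_phase(seq: str, seed: int | np.random.Generator) -> tuple[str, str]:
    """One haplotype pair drawn uniformly from all phase resolutions."""
    _validate(seq)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h1, h2 = list(seq), list(seq)
    first = True
    for i, c in enumerate(seq):
        if not is_het(c):
            continue
        a, b = AMBIGUITY[c]
        if first:
            first = False  # canonical orientation: unordered pairs only
        elif rng.integers(2):
            a, b = b, a
        h1[i], h2[i] = a, b
    return "".join(h1), "".join(h2)


def haploid_consensus(seq: str, seed: int | np.random.Generator) -> str:
    """Haploidified consensus: one uniformly chosen base per het site.

    This reproduces the chimaeric single-sequence representation used by
    haploid genome assemblies, in which the phase between neighbouring
    heterozygous sites is effectively random.
    """
    _validate(seq)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(seq)
    for i, c in enumerate(seq):
        if is_het(c):
            out[i] = AMBIGUITY[c][rng.integers(2)]
    return "".join(out)


def collapse_to_diploid(h1: str, h2: str) -> str:
    """Re-collapse a haplotype pair to its IUPAC diploid sequence."""
    from ._iupac import diploid_code

    if len(h1) != len(h2):
        raise ValueError("haplotypes have unequal lengths")
    return "".join(diploid_code(a, b) for a, b in zip(h1, h2))


# ---------------------------------------------------------------------------
# FASTA convenience I/O

def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
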