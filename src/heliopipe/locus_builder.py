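"""Extraction of short multilocus alignments from filtered genotype calls.

Loci are short (~100-2000 bp) genomic segments spaced at least 2 kb apart,
chosen so that each is approximately recombination-free internally while
neighbouring loci recombine freely -- the sampling units of multispecies
coalescent analyses.  Noncoding loci are scanned out of the complement of
the merged exon annotation; coding loci take one locus per merged coding
region with no length cap.  Alignments are unphased diploid consensus
sequences with heterozygotes as IUPAC ambiguity codes; repeat-overlapping
columns are removed, loci with more than half their cells missing are
rejected, remaining columns with any missing cell are dropped, and loci
with fewer than 10 clean columns are discarded.  Retained loci are grouped
into consecutive blocks (100 or 200 loci) per chromosome region, dropping a
trailing block of fewer than 40.

All coordinates are 0-based half-open internally; VCF (1-based) and GFF3
(1-based closed) are converted on read, BED is native.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._iupac import MISSING, VALID_DIPLOID, alleles, is_het

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of possibly-overlapping 0-based half-open intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if end <= start:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def complement_intervals(intervals: Sequence[Interval], length: int) -> list[Interval]:
    """Complement of merged intervals within ``[0, length)``."""
    out: list[Interval] = []
    cursor = 0
    for start, end in intervals:
        if start > cursor:
            out.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < length:
        out.append((cursor, length))
    return out


@dataclass
class GenomeAnnotation:
    """Chromosome lengths with exon and repeat interval tracks (0-based half-open)."""

    chrom_lengths: dict[str, int]
    exons: dict[str, list[Interval]] = field(default_factory=dict)
    repeats: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for track in (self.exons, self.repeats):
            for chrom, ivals in track.items():
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"intervals on unknown chromosome {chrom!r}")
                length = self.chrom_lengths[chrom]
                for s, e in ivals:
                    if not (0 <= s < e <= length):
                        raise ValueError(f"interval ({s}, {e}) outside {chrom} (len {length})")


def partition_annotation(ann: GenomeAnnotation) -> tuple[dict[str, list[Interval]], dict[str, list[Interval]]]:
    """Split each chromosome into merged coding regions and their complement."""
    coding: dict[str, list[Interval]] = {}
    noncoding: dict[str, list[Interval]] = {}
    for chrom, length in ann.chrom_lengths.items():
        merged = merge_intervals(ann.exons.get(chrom, []))
        coding[chrom] = merged
        noncoding[chrom] = complement_intervals(merged, length)
    return coding, noncoding


@dataclass(frozen=True)
class LocusSpec:
    chrom: str
    start: int  # 0-based half-open
    end: int
    locus_class: str  # "coding" | "noncoding"
    region_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty locus ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def propose_noncoding_loci(
    regions: Sequence[Interval],
    chrom: str,
    region_id: str | None = None,
    min_gap: int = 2000,
    min_span: int = 100,
    max_len: int = 2000,
    prev_end: int | None = None,
) -> list[LocusSpec]:
    """Scan noncoding regions left to right, initiating spaced loci.

    A locus starts at the first position ``p`` of a noncoding region with
    ``p - (end of the previous locus) >= min_gap`` (gap measured end to
    start, also across region boundaries) and at least ``min_span`` bp left
    in the region; it runs to the region end or to ``max_len`` bp, whichever
    comes first.  Multiple loci may come from one region when the gap and
    span conditions recur.
    """
    loci: list[LocusSpec] = []
    rid = region_id if region_id is not None else chrom
    last_end = prev_end  # end of previous locus, None if no locus yet
    for rstart, rend in sorted(regions):
        p = rstart if last_end is None else max(rstart, last_end + min_gap)
        while rend - p >= min_span:
            end = min(rend, p + max_len)
            loci.append(LocusSpec(chrom, p, end, "noncoding", rid))
            last_end = end
            p = last_end + min_gap
    return loci


def propose_coding_loci(
    regions: Sequence[Interval],
    chrom: str,
    region_id: str | None = None,
    min_gap: int = 2000,
    min_span: int = 100,
    prev_end: int | None = None,
) -> list[LocusSpec]:
    """One uncapped locus per coding region, under the same gap/span gates."""
    loci: list[LocusSpec] = []
    rid = region_id if region_id is not None else chrom
    last_end = prev_end
    for rstart, rend in sorted(regions):
        p = rstart if last_end is None else max(rstart, last_end + min_gap)
        if rend - p >= min_span:
            loci.append(LocusSpec(chrom, p, rend, "coding", rid))
            last_end = rend
    return loci


# ---------------------------------------------------------------------------
# alignment construction

@dataclass
class LocusAlignment:
    """Unphased diploid alignment over the retained columns of one locus."""

    spec: LocusSpec
    names: list[str]
    seqs: list[str]
    n_sites: int = 0
    n_informative: int = 0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        if not self.n_sites and self.seqs:
            self.n_sites = len(self.seqs[0])


@dataclass
class Rejection:
    spec: LocusSpec
    reason: str  # "missing>50%" | "<10 sites" | "no columns"


def _informative_columns(matrix: np.ndarray) -> int:
    """Count parsimony-informative columns of an IUPAC genotype matrix.

    A diploid character contributes both alleles to its individual; a column
    is informative when at least two alleles are each carried by at least
    two individuals.
    """
    n_inf = 0
    for col in matrix:
        carriers: dict[str, int] = {}
        for char in col:
            for a in set(alleles(char)):
                carriers[a] = carriers.get(a, 0) + 1
        if sum(1 for c in carriers.values() if c >= 2) >= 2:
            n_inf += 1
    return n_inf


def build_alignment(
    spec: LocusSpec,
    names: Sequence[str],
    matrix: np.ndarray,
    repeats: Sequence[Interval] = (),
    min_sites: int = 10,
    max_missing_frac: float = 0.5,
) -> LocusAlignment | Rejection:
    """Build the cleaned alignment for one locus, or a typed rejection.

    ``matrix`` holds one IUPAC character per (site, individual) over the full
    locus span, with 'N' marking missing genotypes.  Order of operations:
    drop repeat-overlapping columns; reject if the missing fraction over all
    remaining cells exceeds ``max_missing_frac``; drop every column with at
    least one missing cell; reject if fewer than ``min_sites`` columns
    remain.
    """
    matrix = np.asarray(matrix)
    if matrix.shape != (spec.length, len(names)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match locus span {spec.length} x {len(names)}"
        )
    bad = set()
    for char in np.unique(matrix):
        if char not in VALID_DIPLOID:
            bad.add(str(char))
    if bad:
        raise ValueError(f"invalid genotype characters: {sorted(bad)}")

    positions = np.arange(spec.start, spec.end)
    keep = np.ones(spec.length, dtype=bool)
    for rstart, rend in repeats:
        keep &= ~((positions >= rstart) & (positions < rend))
    sub = matrix[keep]
    if sub.size == 0:
        return Rejection(spec, "no columns")
    missing_mask = sub == MISSING
    if missing_mask.mean() > max_missing_frac:
        return Rejection(spec, "missing>50%")
    clean = sub[~missing_mask.any(axis=1)]
    if clean.shape[0] < min_sites:
        return Rejection(spec, "<10 sites")
    seqs = ["".join(clean[:, j]) for j in range(clean.shape[1])]
    return LocusAlignment(
        spec=spec,
        names=list(names),
        seqs=seqs,
        n_sites=clean.shape[0],
        n_informative=_informative_columns(clean),
    )


# ---------------------------------------------------------------------------
# blocks and summaries

@dataclass
class Block:
    region_id: str
    index: int
    loci: list[LocusAlignment]


def group_blocks(
    alignments: Sequence[LocusAlignment],
    block_size: int = 100,
    min_last: int = 40,
) -> tuple[list[Block], list[tuple[str, int]]]:
    """Chunk loci into consecutive genomic-order blocks per chromosome region.

    Returns the blocks and a log of ``(region_id, n_dropped)`` for trailing
    groups smaller than ``min_last``.
    """
    if block_size < 1 or min_last < 1:
        raise ValueError("block_size and min_last must be >= 1")
    by_region: dict[str, list[LocusAlignment]] = {}
    for aln in alignments:
        by_region.setdefault(aln.spec.region_id, []).append(aln)
    blocks: list[Block] = []
    dropped: list[tuple[str, int]] = []
    for region_id in sorted(by_region):
        loci = sorted(by_region[region_id], key=lambda a: (a.spec.chrom, a.spec.start))
        for i in range(0, len(loci), block_size):
            chunk = loci[i : i + block_size]
            if len(chunk) < block_size and len(chunk) < min_last:
                dropped.append((region_id, len(chunk)))
            else:
                blocks.append(Block(region_id=region_id, index=i // block_size, loci=chunk))
    return blocks, dropped


def summarize_loci(alignments: Sequence[LocusAlignment]) -> dict[str, dict[str, float]]:
    """Per-class locus counts with median length and median informative sites."""
    if not alignments:
        raise ValueError("no alignments to summarize")
    out: dict[str, dict[str, float]] = {}
    for cls in sorted({a.spec.locus_class for a in alignments}):
        sub = [a for a in alignments if a.spec.locus_class == cls]
        out[cls] = {
            "count": len(sub),
            "median_length": float(median(a.n_sites for a in sub)),
            "median_informative": float(median(a.n_informative for a in sub)),
        }
    return out


# ---------------------------------------------------------------------------
# output formats

def write_phylip(alignments: Sequence[LocusAlignment], path: str) -> None:
    """Write a multilocus phylip file (one ``n_seq n_sites`` record per locus).

    Sequence labels take the form ``<id>^<individual>`` so that the token
    after the caret resolves through the Imap file.
    """
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f"{len(aln.names)} {aln.n_sites}\n")
            for name, seq in zip(aln.names, aln.seqs):
                fh.write(f"{name}^{name}  {seq}\n")
            fh.write("\n")


def read_phylip(path: str) -> list[tuple[list[str], list[str]]]:
    """Read a multilocus phylip file back as ``(names, seqs)`` per locus."""
    loci: list[tuple[list[str], list[str]]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_seq, n_sites = (int(tok) for tok in lines[i].split())
        names, seqs = [], []
        for j in range(i + 1, i + 1 + n_seq):
            label, seq = lines[j].split()
            names.append(label.split("^")[0])
            seqs.append(seq)
            if len(seq) != n_sites:
                raise ValueError(f"sequence length {len(seq)} != header {n_sites}")
        loci.append((names, seqs))
        i += 1 + n_seq
    return loci


def write_imap(mapping: Mapping[str, str], path: str) -> None:
    """Write an Imap file mapping individual to species, one pair per line."""
    with open(path, "w") as fh:
        for ind in sorted(mapping):
            fh.write(f"{ind}\t{mapping[ind]}\n")


def write_locus_bed(specs: Sequence[LocusSpec], path: str) -> None:
    with open(path, "w") as fh:
        for spec in sorted(specs, key=lambda s: (s.chrom, s.start)):
            fh.write(f"{spec.chrom}\t{spec.start}\t{spec.end}\t{spec.locus_class}\t{spec.region_id}\n")
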