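"""Genotype-level quality filters for VCF-style calls.

Implements the filter cascade used when compiling diploid genotype calls
into coalescent-ready alignments: site quality (QUAL), genotype quality
(GQ), a per-sample depth window anchored at the sample's mean depth
(``max(mean_dp/2, 20) <= DP <= 2*mean_dp``, with a lower floor of 10 for
haploid samples such as the female Z chromosome), and masking of calls near
indels.  Genotypes failing any rule are recoded as missing rather than
dropped, so downstream locus extraction sees a complete site-by-sample
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = None


@dataclass
class GenotypeRecord:
    """One sample's called genotype at one site."""

    chrom: str
    pos: int  # 1-based
    sample: str
    gt: str | None  # "00", "01", "11" (diploid), "0"/"1" (haploid), None = missing
    dp: int = 0
    gq: float = 0.0
    site_qual: float = 0.0
    near_indel: bool = False
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        if self.dp < 0:
            raise ValueError(f"negative depth at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class FilterConfig:
    qual_min: float = 20.0
    gq_min: float = 20.0
    dp_floor_diploid: int = 20
    dp_floor_haploid: int = 10
    dp_mean_low_factor: float = 0.5
    dp_mean_high_factor: float = 2.0
    indel_window_bp: int = 5

    def __post_init__(self) -> None:
        if min(self.qual_min, self.gq_min, self.dp_floor_diploid, self.dp_floor_haploid) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.dp_mean_low_factor <= 0 or self.dp_mean_high_factor <= 0:
            raise ValueError("mean-depth factors must be > 0")


@dataclass
class SampleDepthStats:
    sample: str
    mean_dp: float

    def __post_init__(self) -> None:
        if self.mean_dp <= 0:
            raise ValueError(f"mean_dp must be > 0 for sample {self.sample}")


#: fixed order in which failures are attributed for the report
FILTER_ORDER = ("QUAL", "GQ", "DP", "INDEL")


def depth_bounds(stats: SampleDepthStats, ploidy: int, cfg: FilterConfig = FilterConfig()) -> tuple[float, float]:
    """Per-sample depth window ``(low, high)`` for retained genotypes."""
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")
    floor = cfg.dp_floor_diploid if ploidy == 2 else cfg.dp_floor_haploid
    low = max(stats.mean_dp * cfg.dp_mean_low_factor, floor)
    high = stats.mean_dp * cfg.dp_mean_high_factor
    return low, high


def _indel_intervals(
    indels: Iterable[tuple[str, int] | tuple[str, int, int]],
    window_bp: int,
) -> dict[str, list[tuple[int, int]]]:
    """Masked 1-based closed intervals around indel anchors.

    Each indel is ``(chrom, pos)`` or ``(chrom, pos, ref_len)``; deletions
    (ref_len > 1) mask the window beyond their REF span as well.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for item in indels:
        chrom, pos = item[0], item[1]
        ref_len = item[2] if len(item) > 2 else 1
        out.setdefault(chrom, []).append((pos - window_bp, pos + ref_len - 1 + window_bp))
    for chrom in out:
        out[chrom].sort()
    return out


def mask_near_indels(
    records: Sequence[GenotypeRecord],
    indels: Iterable[tuple[str, int] | tuple[str, int, int]],
    window_bp: int = 5,
) -> list[GenotypeRecord]:
    """Return records with ``near_indel`` set for calls within the window."""
    ivals = _indel_intervals(indels, window_bp)
    out = []
    for rec in records:
        flagged = rec.near_indel
        if not flagged:
            chrom_ivals = ivals.get(rec.chrom)
            if chrom_ivals:
                starts = np.array([s for s, _ in chrom_ivals])
                ends = np.array([e for _, e in chrom_ivals])
                i = int(np.searchsorted(starts, rec.pos, side="right")) - 1
                # overlapping windows: check every interval starting at or before pos
                flagged = bool(np.any((starts[: i + 1] <= rec.pos) & (rec.pos <= ends[: i + 1])))
        out.append(replace(rec, near_indel=flagged))
    return out


def compute_mean_depth(records: Iterable[GenotypeRecord], qual_min: float = 20.0) -> dict[str, SampleDepthStats]:
    """Mean depth per sample over called genotypes at QUAL-passing sites.

    The mean is fixed from this single pass so that the depth window does
    not depend on its own filtering outcome.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in records:
        if rec.gt is MISSING or rec.site_qual < qual_min:
            continue
        sums[rec.sample] = sums.get(rec.sample, 0.0) + rec.dp
        counts[rec.sample] = counts.get(rec.sample, 0) + 1
    return {
        s: SampleDepthStats(sample=s, mean_dp=sums[s] / counts[s])
        for s in sums
        if counts[s] > 0 and sums[s] > 0
    }


def apply_filters(
    records: Sequence[GenotypeRecord],
    stats: Mapping[str, SampleDepthStats],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[GenotypeRecord], dict[str, int]]:
    """Recode failing genotypes as missing; tally failures by first rule hit.

    A genotype is retained iff QUAL >= qual_min, GQ >= gq_min, DP lies in the
    sample's depth window, and the call is not near an indel.  Already-missing
    genotypes pass through untouched and are not tallied.
    """
    tally = {name: 0 for name in FILTER_ORDER}
    bounds: dict[tuple[str, int], tuple[float, float]] = {}
    out: list[GenotypeRecord] = []
    for rec in records:
        if rec.gt is MISSING:
            out.append(rec)
            continue
        if rec.sample not in stats:
            raise KeyError(f"no depth stats for sample {rec.sample!r}")
        key = (rec.sample, rec.ploidy)
        if key not in bounds:
            bounds[key] = depth_bounds(stats[rec.sample], rec.ploidy, cfg)
        low, high = bounds[key]
        failed = None
        if rec.site_qual < cfg.qual_min:
            failed = "QUAL"
        elif rec.gq < cfg.gq_min:
            failed = "GQ"
        elif not (low <= rec.dp <= high):
            failed = "DP"
        elif rec.near_indel:
            failed = "INDEL"
        if failed is None:
            out.append(rec)
        else:
            tally[failed] += 1
            out.append(replace(rec, gt=MISSING))
    return out, tally


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)

def _gt_string(sample_values, ploidy: int) -> str | None:
    alleles = sample_values.get("GT")
    if alleles is None or any(a is None for a in alleles):
        return None
    if ploidy == 1:
        if len(alleles) != 1:
            # diploid-coded hemizygous call: accept if homozygous
            if len(set(alleles)) != 1:
                return None
            alleles = alleles[:1]
        return str(alleles[0])
    if len(alleles) != 2:
        return None
    return "".join(str(a) for a in sorted(alleles))


def read_vcf_records(
    path: str,
    haploid_samples: Iterable[str] = (),
    samples: Sequence[str] | None = None,
) -> tuple[list[GenotypeRecord], list[tuple[str, int, int]]]:
    """Read per-sample genotype records and indel anchors from a VCF.

    Genotypes come from FORMAT/GT; DP and GQ from the FORMAT fields, with a
    fallback to INFO/DP when a sample has no FORMAT/DP.  Returns the records
    plus the list of indel ``(chrom, pos, ref_len)`` anchors observed, for
    use with :func:`mask_near_indels`.
    """
    import pysam

    haploid = set(haploid_samples)
    records: list[GenotypeRecord] = []
    indels: list[tuple[str, int, int]] = []
    with pysam.VariantFile(path) as vcf:
        wanted = list(samples) if samples is not None else list(vcf.header.samples)
        for site in vcf:
            ref = site.ref or ""
            alts = [a for a in (site.alts or ()) if a is not None]
            if any(len(a) != len(ref) for a in alts) or len(ref) > 1:
                indels.append((site.chrom, site.pos, len(ref)))
                continue
            qual = site.qual if site.qual is not None else 0.0
            info_dp = site.info.get("DP") if "DP" in site.info else None
            for name in wanted:
                sv = site.samples[name]
                ploidy = 1 if name in haploid else 2
                gt = _gt_string(sv, ploidy)
                dp = sv.get("DP")
                if dp is None:
                    dp = info_dp if info_dp is not None else 0
                gq = sv.get("GQ")
                records.append(
                    GenotypeRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        sample=name,
                        gt=gt,
                        dp=int(dp),
                        gq=float(gq) if gq is not None else 0.0,
                        site_qual=float(qual),
                        ploidy=ploidy,
                    )
                )
    return records, indels


def filter_vcf(
    in_path: str,
    out_path: str,
    cfg: FilterConfig = FilterConfig(),
    haploid_samples: Iterable[str] = (),
) -> dict[str, int]:
    """Apply the filter cascade to a VCF, writing failures as missing GTs."""
    records, indels = read_vcf_records(in_path, haploid_samples=haploid_samples)
    records = mask_near_indels(records, indels, cfg.indel_window_bp)
    stats = compute_mean_depth(records, cfg.qual_min)
    filtered, tally = apply_filters(records, stats, cfg)
    missing = {(r.chrom, r.pos, r.sample) for r in filtered if r.gt is MISSING}

    import pysam

    with pysam.VariantFile(in_path) as vcf_in:
        with pysam.VariantFile(out_path, "w", header=vcf_in.header) as vcf_out:
            for site in vcf_in:
                for name in site.samples:
                    if (site.chrom, site.pos, name) in missing:
                        alleles = site.samples[name].get("GT") or (None,)
                        site.samples[name]["GT"] = tuple(None for _ in alleles)
                vcf_out.write(site)
    return tally
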