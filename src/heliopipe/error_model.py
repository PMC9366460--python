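"""Genotype-calling error model under a binomial read model.

At a biallelic site covered by ``n`` reads, of which ``k`` support the
alternative allele, maximum-likelihood genotype calling compares the three
binomial likelihoods

    L(00 | k) = C(n,k) (1-eps)^(n-k) eps^k
    L(01 | k) = C(n,k) (1/2)^n
    L(11 | k) = C(n,k) (1-eps)^k eps^(n-k)

where ``eps`` is the per-read base-calling error probability, 0 denotes the
reference allele and 1 the alternative allele.  The genotype-calling error
rate for a true genotype is the probability, over read outcomes
``k = 0..n``, that the ML call differs from the truth.  Because calling is a
threshold rule on a discrete outcome, this error rate is *not* monotone in
either ``n`` or ``eps``: lowering the base-calling error, or adding a read,
can move the decision thresholds so that more outcomes are miscalled.  This
module computes those error rates exactly and uses them to recommend
minimum-depth filters, and estimates ``eps`` empirically from allele-depth
(AD) counts at deeply covered homozygous sites.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


def _binom_pmf(ks: np.ndarray | int, n: int, p: float) -> np.ndarray | float:
    """Stable Binomial(n, p) pmf: exact integer coefficients, log-space powers.

    Well-behaved for subnormal ``p`` where library betainc-based pmfs can
    overflow; exact to ~1 ulp relative for the n <= a-few-hundred regime used
    here.
    """
    scalar = np.isscalar(ks)
    ks_arr = np.atleast_1d(np.asarray(ks, dtype=np.int64))
    out = np.zeros(ks_arr.shape, dtype=float)
    if p == 0.0:
        out[ks_arr == 0] = 1.0
    elif p == 1.0:
        out[ks_arr == n] = 1.0
    else:
        logp, log1mp = math.log(p), math.log1p(-p)
        for i, k in enumerate(ks_arr):
            out[i] = math.comb(n, int(k)) * math.exp(k * logp + (n - k) * log1mp)
    return float(out[0]) if scalar else out



class GenotypeClass(enum.Enum):
    """Diploid genotype at a biallelic site (0 = reference allele)."""

    HOM_REF = "00"
    HET = "01"
    HOM_ALT = "11"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class HaploidClass(enum.Enum):
    """Haploid genotype (single-copy chromosomes, e.g. the female Z)."""

    REF = "0"
    ALT = "1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: fixed tie-break preference when likelihoods are exactly equal
_TIE_ORDER = (GenotypeClass.HET, GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT)


class NoQualifyingDataError(ValueError):
    """Raised when an empirical estimate has no records to work with."""


def _check_epsilon(epsilon: float) -> None:
    if not (0.0 <= epsilon < 0.5):
        raise ValueError(f"epsilon must be in [0, 0.5), got {epsilon}")


def _check_read_count(k: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"read depth must be >= 1, got {n}")
    if not (0 <= k <= n):
        raise ValueError(f"alternative read count must satisfy 0 <= k <= n, got k={k}, n={n}")


def genotype_likelihoods(k: int, n: int, epsilon: float) -> dict[GenotypeClass, float]:
    """Binomial likelihoods of the three diploid genotypes given read data.

    Parameters
    ----------
    k
        Number of reads supporting the alternative allele.
    n
        Read depth (total number of reads).
    epsilon
        Per-read base-calling error probability, in [0, 0.5).
    """
    _check_epsilon(epsilon)
    _check_read_count(k, n)
    return {
        GenotypeClass.HOM_REF: float(_binom_pmf(k, n, epsilon)),
        GenotypeClass.HET: float(_binom_pmf(k, n, 0.5)),
        # reflected pmf: exactly symmetric to HOM_REF even for subnormal epsilon
        GenotypeClass.HOM_ALT: float(_binom_pmf(n - k, n, epsilon)),
    }


def call_genotype(k: int, n: int, epsilon: float) -> GenotypeClass:
    """ML genotype call: the genotype with the highest likelihood.

    Exact likelihood ties (possible only at boundary read counts) are broken
    by the fixed preference HET > HOM_REF > HOM_ALT.
    """
    like = genotype_likelihoods(k, n, epsilon)
    best = max(like.values())
    for gt in _TIE_ORDER:
        if like[gt] == best:
            return gt
    raise AssertionError("unreachable")


def _call_table(n: int, epsilon: float) -> np.ndarray:
    """Vector of calls over k = 0..n, coded 0=HOM_REF, 1=HET, 2=HOM_ALT."""
    ks = np.arange(n + 1)
    l00 = _binom_pmf(ks, n, epsilon)
    l01 = _binom_pmf(ks, n, 0.5)
    l11 = _binom_pmf(n - ks, n, epsilon)
    stacked = np.stack([l01, l00, l11])  # tie order: HET first, then HOM_REF
    winner = np.argmax(stacked, axis=0)  # argmax takes the first maximum
    return np.array([1, 0, 2])[winner]


def genotype_error_rate(true_gt: GenotypeClass, n: int, epsilon: float) -> float:
    """Probability that the ML call differs from the true genotype.

    Averages the miscall indicator over the read outcome ``k ~ Binomial``:
    with success probability ``epsilon`` for a true homozygote (reference or,
    by symmetry, alternative) and ``1/2`` for a true heterozygote.
    """
    _check_epsilon(epsilon)
    if n < 1:
        raise ValueError(f"read depth must be >= 1, got {n}")
    calls = _call_table(n, epsilon)
    ks = np.arange(n + 1)
    if true_gt is GenotypeClass.HOM_REF:
        pk = _binom_pmf(ks, n, epsilon)
        wrong = calls != 0
    elif true_gt is GenotypeClass.HET:
        pk = _binom_pmf(ks, n, 0.5)
        wrong = calls != 1
    elif true_gt is GenotypeClass.HOM_ALT:
        pk = _binom_pmf(n - ks, n, epsilon)
        wrong = calls != 2
    else:  # pragma: no cover
        raise TypeError(f"not a GenotypeClass: {true_gt!r}")
    return float(pk[wrong].sum())


# ---------------------------------------------------------------------------
# haploid mode (single-copy chromosomes: the Z in females)

def haploid_likelihoods(k: int, n: int, epsilon: float) -> dict[HaploidClass, float]:
    """Likelihoods of the two haploid genotypes given k of n alternative reads."""
    _check_epsilon(epsilon)
    _check_read_count(k, n)
    return {
        HaploidClass.REF: float(_binom_pmf(k, n, epsilon)),
        HaploidClass.ALT: float(_binom_pmf(n - k, n, epsilon)),
    }


def call_haploid(k: int, n: int, epsilon: float) -> HaploidClass:
    """ML haploid call; ties (k = n/2) resolved toward REF."""
    like = haploid_likelihoods(k, n, epsilon)
    if like[HaploidClass.REF] >= like[HaploidClass.ALT]:
        return HaploidClass.REF
    return HaploidClass.ALT


def haploid_error_rate(true_gt: HaploidClass, n: int, epsilon: float) -> float:
    """Miscall probability for a haploid genotype; symmetric in REF/ALT."""
    _check_epsilon(epsilon)
    if n < 1:
        raise ValueError(f"read depth must be >= 1, got {n}")
    ks = np.arange(n + 1)
    l0 = _binom_pmf(ks, n, epsilon)
    l1 = _binom_pmf(n - ks, n, epsilon)
    call_is_ref = l0 >= l1
    if true_gt is HaploidClass.REF:
        return float(l0[~call_is_ref].sum())
    return float(l1[call_is_ref].sum())


# ---------------------------------------------------------------------------
# depth profiles and filter recommendation

@dataclass
class DepthErrorProfile:
    """Genotype-calling error per read depth for a fixed base-calling error."""

    epsilon: float
    depths: np.ndarray
    error_hom: np.ndarray
    error_het: np.ndarray

    def to_rows(self) -> list[tuple[int, float, float]]:
        return list(zip(self.depths.tolist(), self.error_hom.tolist(), self.error_het.tolist()))


def error_profile(epsilon: float, depths: Iterable[int]) -> DepthErrorProfile:
    """Tabulate homozygote and heterozygote calling error across read depths."""
    depth_arr = np.asarray(sorted(set(int(d) for d in depths)), dtype=int)
    if depth_arr.size == 0:
        raise ValueError("depth range is empty")
    hom = np.array([genotype_error_rate(GenotypeClass.HOM_REF, n, epsilon) for n in depth_arr])
    het = np.array([genotype_error_rate(GenotypeClass.HET, n, epsilon) for n in depth_arr])
    return DepthErrorProfile(epsilon=epsilon, depths=depth_arr, error_hom=hom, error_het=het)


UNATTAINABLE = None


def recommend_min_depth(epsilon: float, target_error: float, n_max: int) -> int | None:
    """Smallest depth floor guaranteeing the target calling error.

    Returns the smallest ``n*`` such that for *every* depth in
    ``[n*, n_max]`` the worse of the homozygote and heterozygote calling
    errors is at most ``target_error``.  Because the error is non-monotone in
    depth, the whole suffix must be checked, not just ``n*`` itself.  Returns
    ``None`` when no such depth exists up to ``n_max``.
    """
    if target_error <= 0:
        raise ValueError(f"target_error must be > 0, got {target_error}")
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    prof = error_profile(epsilon, range(1, n_max + 1))
    worst = np.maximum(prof.error_hom, prof.error_het)
    # suffix maximum: worst error over all depths >= n
    suffix = np.maximum.accumulate(worst[::-1])[::-1]
    ok = np.nonzero(suffix <= target_error)[0]
    if ok.size == 0:
        return UNATTAINABLE
    return int(prof.depths[ok[0]])


# ---------------------------------------------------------------------------
# empirical base-calling error from AD counts at deep homozygous sites

@dataclass
class HomozygousSiteRecord:
    """One sample's homozygous genotype call with its allele depths.

    ``ad`` lists read counts per allele, allele 0 being the VCF REF.
    """

    chrom: str
    pos: int  # 1-based
    gt: GenotypeClass
    dp: int
    ad: tuple[int, ...]


@dataclass
class BaseErrorEstimate:
    """Base-calling error estimated separately for GT=00 and GT=11 sites."""

    epsilon_homref: float | None
    epsilon_homalt: float | None
    erroneous_reads: dict[str, int] = field(default_factory=dict)
    total_depth: dict[str, int] = field(default_factory=dict)

    @property
    def pooled(self) -> float:
        """Error pooled over both homozygous classes."""
        err = sum(self.erroneous_reads.values())
        tot = sum(self.total_depth.values())
        if tot == 0:
            raise NoQualifyingDataError("no qualifying homozygous records")
        return err / tot


def _in_mask(chrom: str, pos: int, mask: Mapping[str, Sequence[tuple[int, int]]] | None) -> bool:
    """True if 1-based pos falls in a 0-based half-open masked interval."""
    if mask is None:
        return False
    for start, end in mask.get(chrom, ()):
        if start <= pos - 1 < end:
            return True
    return False


def estimate_base_error(
    records: Iterable[HomozygousSiteRecord],
    min_depth: int = 50,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> BaseErrorEstimate:
    """Estimate the per-read base-calling error from homozygous calls.

    Restricted to homozygous calls with ``dp >= min_depth`` lying outside the
    excluded (typically repeat-annotated) intervals.  For each retained
    record the erroneous reads are ``dp`` minus the reads supporting the
    called allele; the estimate is the ratio of erroneous reads to depth,
    both summed over sites, computed separately for GT=00 and GT=11.
    Multi-allelic records (more than two AD entries) are skipped: the
    procedure is defined for biallelic calls.
    """
    err = {"00": 0, "11": 0}
    tot = {"00": 0, "11": 0}
    any_record = False
    for rec in records:
        if rec.gt not in (GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT):
            continue
        if rec.dp < min_depth or len(rec.ad) > 2:
            continue
        if _in_mask(rec.chrom, rec.pos, exclude):
            continue
        if sum(rec.ad) > rec.dp:
            raise ValueError(f"AD sums above DP at {rec.chrom}:{rec.pos}")
        supporting = rec.ad[0] if rec.gt is GenotypeClass.HOM_REF else rec.ad[1]
        key = rec.gt.value
        err[key] += rec.dp - supporting
        tot[key] += rec.dp
        any_record = True
    if not any_record:
        raise NoQualifyingDataError("no homozygous records pass the depth/mask filters")
    return BaseErrorEstimate(
        epsilon_homref=err["00"] / tot["00"] if tot["00"] else None,
        epsilon_homalt=err["11"] / tot["11"] if tot["11"] else None,
        erroneous_reads=err,
        total_depth=tot,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo check of the analytic error rates

def simulate_calling_error(
    true_gt: GenotypeClass,
    n: int,
    epsilon: float,
    n_sites: int,
    rng: np.random.Generator,
) -> float:
    """Empirical miscall frequency over simulated read outcomes.

    Draws ``n_sites`` read outcomes ``k`` from the binomial read channel and
    applies the ML call to each; serves as a simulation cross-check of
    :func:`genotype_error_rate`.
    """
    _check_epsilon(epsilon)
    if true_gt is GenotypeClass.HET:
        p = 0.5
    elif true_gt is GenotypeClass.HOM_REF:
        p = epsilon
    else:
        p = 1.0 - epsilon
    ks = rng.binomial(n, p, size=n_sites)
    calls = _call_table(n, epsilon)
    truth_code = {GenotypeClass.HOM_REF: 0, GenotypeClass.HET: 1, GenotypeClass.HOM_ALT: 2}[true_gt]
    return float(np.mean(calls[ks] != truth_code))
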