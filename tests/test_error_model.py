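"""Exact and statistical checks of the binomial genotype-calling error model."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heliopipe import error_model as em
from heliopipe.error_model import GenotypeClass as G


def exact_call(k: int, n: int, eps: Fraction) -> str:
    """Independent oracle: ML call via exact rational arithmetic."""
    l00 = (1 - eps) ** (n - k) * eps**k
    l01 = Fraction(1, 2**n)
    l11 = (1 - eps) ** k * eps ** (n - k)
    best = max(l00, l01, l11)
    if l01 == best:  # tie preference HET > HOM_REF > HOM_ALT
        return "01"
    return "00" if l00 == best else "11"


def exact_error(true_gt: str, n: int, eps: Fraction) -> Fraction:
    total = Fraction(0)
    for k in range(n + 1):
        if true_gt == "00":
            pk = comb(n, k) * (1 - eps) ** (n - k) * eps**k
        elif true_gt == "01":
            pk = Fraction(comb(n, k), 2**n)
        else:
            pk = comb(n, k) * (1 - eps) ** k * eps ** (n - k)
        if exact_call(k, n, eps) != true_gt:
            total += pk
    return total


class TestLikelihoods:
    def test_direct_evaluation(self):
        like = em.genotype_likelihoods(0, 2, 0.01)
        assert like[G.HOM_REF] == pytest.approx(0.9801)
        assert like[G.HET] == pytest.approx(0.25)
        assert like[G.HOM_ALT] == pytest.approx(0.0001)

    def test_error_free_reads(self):
        like = em.genotype_likelihoods(0, 5, 0.0)
        assert like[G.HOM_REF] == 1.0
        assert like[G.HET] == pytest.approx(1 / 32)
        assert like[G.HOM_ALT] == 0.0

    @given(n=st.integers(1, 30).map(lambda x: 2 * x), eps=st.floats(0.0, 0.49))
    @settings(deadline=None)
    def test_symmetric_k_swaps_homozygotes(self, n, eps):
        k = n // 2
        like = em.genotype_likelihoods(k, n, eps)
        assert like[G.HOM_REF] == pytest.approx(like[G.HOM_ALT], rel=1e-12)

    @given(k=st.integers(0, 20), n=st.integers(1, 20), eps=st.floats(0.0, 0.49))
    @settings(deadline=None)
    def test_k_reflection_swaps_likelihoods(self, k, n, eps):
        k = min(k, n)
        a = em.genotype_likelihoods(k, n, eps)
        b = em.genotype_likelihoods(n - k, n, eps)
        assert a[G.HOM_REF] == pytest.approx(b[G.HOM_ALT], rel=1e-9, abs=1e-300)
        assert a[G.HET] == pytest.approx(b[G.HET], rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            em.genotype_likelihoods(0, 2, 0.5)
        with pytest.raises(ValueError):
            em.genotype_likelihoods(3, 2, 0.01)
        with pytest.raises(ValueError):
            em.genotype_likelihoods(0, 0, 0.01)


class TestCalling:
    @pytest.mark.parametrize(
        "k,n,eps,expected",
        [
            (1, 7, 0.01, G.HOM_REF),  # 0.99^6 * 0.01 beats 0.5^7
            (1, 6, 0.01, G.HET),  # one alt read in six flips the call
            (0, 1, 0.1, G.HOM_REF),
            (7, 7, 0.01, G.HOM_ALT),
        ],
    )
    def test_known_calls(self, k, n, eps, expected):
        assert em.call_genotype(k, n, eps) is expected

    @given(k=st.integers(0, 25), n=st.integers(1, 25), eps=st.sampled_from(
        [Fraction(0), Fraction(1, 1000), Fraction(1, 200), Fraction(1, 100), Fraction(1, 10)]
    ))
    @settings(deadline=None)
    def test_matches_exact_rational_oracle(self, k, n, eps):
        k = min(k, n)
        assert em.call_genotype(k, n, float(eps)).value == exact_call(k, n, eps)

    def test_tie_breaks_toward_het(self):
        # eps = 0.5 excluded, but a tie occurs at eps where (1-eps)^n = 2^-n has no
        # float solution; construct one at k = n/2 with eps chosen so L00 == L11 < L01
        like = em.genotype_likelihoods(1, 2, 0.1)
        assert like[G.HOM_REF] == like[G.HOM_ALT]
        assert em.call_genotype(1, 2, 0.1) is G.HET


class TestErrorRate:
    @pytest.mark.parametrize(
        "true_gt,n,eps,expected,tol",
        [
            (G.HOM_REF, 7, 0.01, 0.0020, 5e-5),
            (G.HOM_REF, 7, 0.005, 0.0345, 5e-5),
            (G.HOM_REF, 2, 0.01, 0.0199, 1e-6),
            (G.HOM_REF, 6, 0.01, 0.0585, 5e-5),
            (G.HOM_REF, 20, 0.001, 1.1e-6, 1e-7),
            (G.HET, 20, 0.001, 4.0e-4, 5e-6),
        ],
    )
    def test_reported_error_rates(self, true_gt, n, eps, expected, tol):
        assert em.genotype_error_rate(true_gt, n, eps) == pytest.approx(expected, abs=tol)

    def test_zero_epsilon_is_error_free_for_homozygotes(self):
        for n in range(1, 6):
            assert em.genotype_error_rate(G.HOM_REF, n, 0.0) == 0.0

    def test_het_error_at_zero_epsilon_is_two_to_one_minus_n(self):
        # only the all-0 and all-1 read outcomes are miscalled
        for n in range(2, 12):
            assert em.genotype_error_rate(G.HET, n, 0.0) == pytest.approx(2.0 ** (1 - n))

    @given(n=st.integers(1, 40), eps=st.floats(0.0, 0.49))
    @settings(deadline=None)
    def test_hom_alt_symmetry(self, n, eps):
        assert em.genotype_error_rate(G.HOM_ALT, n, eps) == pytest.approx(
            em.genotype_error_rate(G.HOM_REF, n, eps), rel=1e-9, abs=1e-15
        )

    @pytest.mark.parametrize("true_gt,n,eps", [
        (G.HOM_REF, 7, Fraction(1, 100)),
        (G.HOM_REF, 20, Fraction(1, 1000)),
        (G.HET, 33, Fraction(1, 250)),
        (G.HOM_REF, 100, Fraction(3, 1000)),
        (G.HET, 100, Fraction(1, 100)),
    ])
    def test_within_1e12_of_exact_arithmetic(self, true_gt, n, eps):
        exact = float(exact_error(true_gt.value, n, eps))
        assert abs(em.genotype_error_rate(true_gt, n, float(eps)) - exact) < 1e-12

    def test_non_monotone_in_epsilon_and_depth(self):
        # halving the base error raises the calling error at n = 7 ...
        assert em.genotype_error_rate(G.HOM_REF, 7, 0.005) > em.genotype_error_rate(G.HOM_REF, 7, 0.01)
        # ... and the error rises with depth from n = 2 to 6 before dropping at 7
        e2 = em.genotype_error_rate(G.HOM_REF, 2, 0.01)
        e6 = em.genotype_error_rate(G.HOM_REF, 6, 0.01)
        e7 = em.genotype_error_rate(G.HOM_REF, 7, 0.01)
        assert e6 > e2 > e7

    def test_monte_carlo_agrees_with_analytic(self, rng):
        for true_gt, n, eps in [(G.HOM_REF, 7, 0.01), (G.HET, 20, 0.001)]:
            analytic = em.genotype_error_rate(true_gt, n, eps)
            n_sites = 10**6
            empirical = em.simulate_calling_error(true_gt, n, eps, n_sites, rng)
            se = np.sqrt(analytic * (1 - analytic) / n_sites)
            assert abs(empirical - analytic) <= 3 * se + 1e-12


class TestProfileAndRecommendation:
    def test_profile_tabulates_both_genotypes(self):
        prof = em.error_profile(0.01, range(2, 8))
        assert prof.depths.tolist() == [2, 3, 4, 5, 6, 7]
        assert prof.error_hom[0] == pytest.approx(0.0199)
        assert prof.error_hom[4] == pytest.approx(0.0585, abs=5e-5)

    def test_zero_epsilon_profile_hom_errors_vanish(self):
        prof = em.error_profile(0.0, range(1, 6))
        assert np.all(prof.error_hom == 0.0)

    def test_recommended_floor_achieves_paper_bound(self):
        n_star = em.recommend_min_depth(0.001, 5e-4, 60)
        assert n_star is not None and n_star <= 20
        assert em.genotype_error_rate(G.HET, 20, 0.001) <= 5e-4

    def test_zero_epsilon_closed_form(self):
        # at eps = 0 only the het error 2^(1-n) remains
        n_star = em.recommend_min_depth(0.0, 1e-3, 60)
        assert 2.0 ** (1 - n_star) <= 1e-3
        assert 2.0 ** (1 - (n_star - 1)) > 1e-3

    def test_unattainable_target_is_signalled(self):
        assert em.recommend_min_depth(0.3, 1e-9, 10) is None


class TestHaploidMode:
    def test_single_read_calls_its_base(self):
        assert em.call_haploid(0, 1, 0.1) is em.HaploidClass.REF
        assert em.call_haploid(1, 1, 0.1) is em.HaploidClass.ALT

    def test_error_matches_exact_binomial_tail(self):
        # majority vote: miscall iff more than half the reads are errors
        for n in (5, 10, 21):
            e_ref = em.haploid_error_rate(em.HaploidClass.REF, n, 0.01)
            exact = float(
                sum(
                    Fraction(comb(n, k)) * Fraction(1, 100) ** k * Fraction(99, 100) ** (n - k)
                    for k in range(n + 1)
                    if not exact_haploid_ref_called(k, n)
                )
            )
            assert e_ref == pytest.approx(exact, abs=1e-12)

    def test_error_symmetric_at_odd_depths(self):
        # odd depths have no k = n/2 tie, so REF and ALT errors coincide;
        # at even depths the REF-favouring tie-break makes ALT slightly worse
        for n in (5, 11, 21):
            assert em.haploid_error_rate(em.HaploidClass.REF, n, 0.01) == pytest.approx(
                em.haploid_error_rate(em.HaploidClass.ALT, n, 0.01)
            )
        assert em.haploid_error_rate(em.HaploidClass.ALT, 10, 0.01) > em.haploid_error_rate(
            em.HaploidClass.REF, 10, 0.01
        )


def exact_haploid_ref_called(k: int, n: int) -> bool:
    eps = Fraction(1, 100)
    l0 = (1 - eps) ** (n - k) * eps**k
    l1 = (1 - eps) ** k * eps ** (n - k)
    return l0 >= l1


class TestBaseErrorEstimate:
    def rec(self, pos, gt, dp, ad, chrom="chr1"):
        return em.HomozygousSiteRecord(chrom=chrom, pos=pos, gt=gt, dp=dp, ad=ad)

    def test_hand_counted_ratio(self):
        records = [
            self.rec(10, em.GenotypeClass.HOM_REF, 60, (59, 1)),
            self.rec(20, em.GenotypeClass.HOM_REF, 40, (40, 0)),  # below min depth
        ]
        est = em.estimate_base_error(records, min_depth=50)
        assert est.epsilon_homref == pytest.approx(1 / 60)
        assert est.epsilon_homalt is None

    def test_all_supporting_reads_give_zero(self):
        est = em.estimate_base_error([self.rec(1, em.GenotypeClass.HOM_ALT, 80, (0, 80))])
        assert est.epsilon_homalt == 0.0

    def test_two_percent_example(self):
        est = em.estimate_base_error([self.rec(5, em.GenotypeClass.HOM_REF, 100, (98, 2))])
        assert est.epsilon_homref == pytest.approx(0.02)

    def test_masked_positions_are_excluded(self):
        records = [
            self.rec(100, em.GenotypeClass.HOM_REF, 60, (59, 1)),
            self.rec(200, em.GenotypeClass.HOM_REF, 60, (54, 6)),
        ]
        est = em.estimate_base_error(records, exclude={"chr1": [(150, 250)]})
        assert est.epsilon_homref == pytest.approx(1 / 60)

    def test_no_qualifying_records_raises(self):
        with pytest.raises(em.NoQualifyingDataError):
            em.estimate_base_error([self.rec(1, em.GenotypeClass.HOM_REF, 10, (10, 0))])
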