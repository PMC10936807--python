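"""Scoring model: per-base errors, multinomial likelihoods, posteriors,
likelihood ratios and their invariants."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrtag.scoring import (
    ReadObservation,
    likelihood_ratio,
    log10_multinomial_prob,
    log10_multinomial_prob_global,
    multinomial_prob_global,
    per_base_error,
    posterior,
    score_read,
    uniform_prior,
)

from conftest import make_phase_set, pv


def obs(base: str, e: float, alleles=("A", "G"), pos=100) -> ReadObservation:
    return ReadObservation(pv(pos, alleles), base, e)


def exact_multinomial(k_m: int, k_nm: int, eps: Fraction) -> Fraction:
    """Arbitrary-precision oracle for the count-based multinomial."""
    n = k_m + k_nm
    coeff = Fraction(math.factorial(n), math.factorial(k_m) * math.factorial(k_nm))
    return coeff * (eps / 3) ** k_nm * (1 - eps) ** k_m


class TestPerBaseError:
    @pytest.mark.parametrize("q,expected", [(20, 0.01), (0, 1.0), (30, 0.001), (10, 0.1)])
    def test_phred_inversion(self, q, expected):
        assert per_base_error(q) == pytest.approx(expected, rel=1e-12)

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            per_base_error(-1)


class TestGlobalMultinomial:
    def test_two_matches_no_mismatch(self):
        assert multinomial_prob_global(2, 0, 0.03) == pytest.approx(0.9409, rel=1e-12)

    def test_one_each_matches_exact_oracle(self):
        expected = float(exact_multinomial(1, 1, Fraction(3, 100)))
        assert multinomial_prob_global(1, 1, 0.03) == pytest.approx(expected, rel=1e-12)
        assert multinomial_prob_global(1, 1, 0.03) == pytest.approx(0.0194, rel=1e-12)

    def test_empty_product_is_one(self):
        assert multinomial_prob_global(0, 0, 0.03) == 1.0

    def test_coefficient_can_be_disabled(self):
        with_c = multinomial_prob_global(1, 1, 0.03, use_coefficient=True)
        without = multinomial_prob_global(1, 1, 0.03, use_coefficient=False)
        assert with_c == pytest.approx(2 * without, rel=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.1, 1.5])
    def test_epsilon_domain(self, eps):
        with pytest.raises(ValueError):
            multinomial_prob_global(1, 1, eps)

    @pytest.mark.parametrize("k_m,k_nm", [(km, knm) for km in range(8) for knm in range(8)
                                          if 0 < km + knm <= 10])
    def test_matches_exact_fraction_oracle(self, k_m, k_nm):
        eps = Fraction(1, 50)
        expected = float(exact_multinomial(k_m, k_nm, eps))
        assert multinomial_prob_global(k_m, k_nm, 0.02) == pytest.approx(expected, rel=1e-10)


class TestPerBaseMultinomial:
    def test_constant_error_reduces_to_global_form(self):
        """Oracle equivalence: with every site at the same error rate the
        per-base sum equals the count-based multinomial, exhaustively for
        n <= 10."""
        eps = 0.02
        for n in range(1, 11):
            for k_m in range(n + 1):
                observations = ([obs("A", eps)] * k_m           # matches h1
                                + [obs("T", eps)] * (n - k_m))  # matches neither
                got = log10_multinomial_prob(observations, 0)
                want = log10_multinomial_prob_global(k_m, n - k_m, eps)
                assert got == pytest.approx(want, abs=1e-12, rel=1e-12)

    def test_empty_observation_list(self):
        assert log10_multinomial_prob([], 0) == 0.0

    def test_single_matching_observation(self):
        assert log10_multinomial_prob([obs("A", 0.01)], 0) == pytest.approx(
            math.log10(0.99), abs=1e-12)

    def test_error_probability_one_is_clamped_not_fatal(self):
        value = log10_multinomial_prob([obs("A", 1.0)], 0)
        assert np.isfinite(value)


class TestPosteriorAndLR:
    def test_posterior_odds_example(self):
        post = posterior([math.log10(0.9), math.log10(0.1)], [0.5, 0.5])
        assert 10 ** post[0] == pytest.approx(9.0, rel=1e-10)
        assert 10 ** post[1] == pytest.approx(1 / 9, rel=1e-10)

    def test_equal_probabilities_are_symmetric(self):
        post = posterior([math.log10(0.4)] * 2, [0.5, 0.5])
        assert all(10 ** p == pytest.approx(1.0, rel=1e-10) for p in post)
        post3 = posterior([math.log10(0.2)] * 3, [1 / 3] * 3)
        assert all(10 ** p == pytest.approx(0.5, rel=1e-10) for p in post3)

    def test_likelihood_ratio_squares_the_diploid_odds(self):
        post = posterior([math.log10(0.9), math.log10(0.1)], [0.5, 0.5])
        lrs = likelihood_ratio(post)
        assert 10 ** lrs[0] == pytest.approx(81.0, rel=1e-10)
        assert 10 ** lrs[1] == pytest.approx(1 / 81, rel=1e-10)
        assert lrs[0] == pytest.approx(1.9085, abs=5e-5)

    def test_tied_posteriors_give_llr_zero(self):
        lrs = likelihood_ratio([math.log10(0.5)] * 2)
        assert lrs == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_extreme_ratio_stays_finite_and_monotone(self):
        lr_big = likelihood_ratio([0.0, -300.0])[0]
        lr_small = likelihood_ratio([0.0, -30.0])[0]
        assert np.isfinite(lr_big) and lr_big > lr_small

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            posterior([0.0], [1.0])
        with pytest.raises(ValueError):
            likelihood_ratio([0.0])

    def test_diploid_closed_form_on_random_pairs(self):
        """For l=2 with uniform priors, log10 LR_best = 2 * (log10 P_best -
        log10 P_other)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            lp = np.log10(rng.uniform(1e-12, 1.0, size=2))
            lrs = likelihood_ratio(posterior(list(lp), [0.5, 0.5]))
            best = int(np.argmax(lrs))
            other = 1 - best
            assert lrs[best] == pytest.approx(2 * (lp[best] - lp[other]),
                                              abs=1e-9, rel=1e-9)


class TestUniformPrior:
    @pytest.mark.parametrize("l,expected", [(2, 0.5), (4, 0.25), (1, 1.0)])
    def test_values(self, l, expected):
        assert uniform_prior(l) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            uniform_prior(0)


class TestScoreRead:
    def test_all_matches_tag_first_haplotype(self):
        observations = [obs("A", 0.01, pos=p) for p in (100, 200, 300)]
        score = score_read(observations, make_phase_set())
        assert score.best_haplotype == 0
        assert score.n_matches_best == 3 and score.n_mismatches_best == 0
        assert score.llr > 0 and not score.tie
        assert score.n_matches_best + score.n_mismatches_best == score.n_variants

    def test_base_matching_neither_haplotype_ties(self):
        score = score_read([obs("T", 0.01)], make_phase_set())
        assert score.tie
        assert score.llr == pytest.approx(0.0, abs=1e-9)

    def test_balanced_split_ties(self):
        observations = [obs("A", 0.01, pos=100), obs("G", 0.01, pos=200)]
        score = score_read(observations, make_phase_set())
        assert score.tie

    def test_all_two_site_configurations_against_brute_force(self):
        """Exhaustive check of tie/winner structure over every 2-site
        base configuration at equal error."""
        e = 0.02
        for b1 in "ACGT":
            for b2 in "ACGT":
                observations = [obs(b1, e, pos=100), obs(b2, e, pos=200)]
                score = score_read(observations, make_phase_set())
                m1 = (b1 == "A") + (b2 == "A")
                m2 = (b1 == "G") + (b2 == "G")
                if m1 == m2:
                    assert score.tie
                else:
                    assert not score.tie
                    assert score.best_haplotype == (0 if m1 > m2 else 1)

    def test_global_mode_matches_per_base_mode_at_constant_error(self):
        observations = [obs("A", 0.03, pos=100), obs("G", 0.03, pos=200),
                        obs("A", 0.03, pos=300)]
        per_base = score_read(observations, make_phase_set())
        global_ = score_read(observations, make_phase_set(), epsilon_global=0.03,
                             per_base_mode=False)
        assert per_base.llr == pytest.approx(global_.llr, abs=1e-9)
        assert per_base.best_haplotype == global_.best_haplotype

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            score_read([], make_phase_set())

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("ACGT"), min_size=1, max_size=8),
           st.integers(2, 4), st.randoms(use_true_random=False))
    def test_label_permutation_equivariance(self, bases, ploidy, rnd):
        """Permuting the haplotype order permutes scores identically."""
        alleles = tuple("ACGT"[:ploidy])
        perm = list(range(ploidy))
        rnd.shuffle(perm)
        permuted = tuple(alleles[p] for p in perm)
        obs_a = [ReadObservation(pv(100 + 10 * i, alleles), b, 0.02)
                 for i, b in enumerate(bases)]
        obs_b = [ReadObservation(pv(100 + 10 * i, permuted), b, 0.02)
                 for i, b in enumerate(bases)]
        sa = score_read(obs_a, make_phase_set(ploidy=ploidy))
        sb = score_read(obs_b, make_phase_set(ploidy=ploidy))
        for new_idx, old_idx in enumerate(perm):
            assert sb.lr_by_haplotype[new_idx] == pytest.approx(
                sa.lr_by_haplotype[old_idx], abs=1e-9)
        assert sa.llr == pytest.approx(sb.llr, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("AG"), min_size=1, max_size=10))
    def test_adding_a_match_never_decreases_best_llr(self, bases):
        observations = [obs(b, 0.02, pos=100 + 10 * i) for i, b in enumerate(bases)]
        before = score_read(observations, make_phase_set())
        extra = obs(("A", "G")[before.best_haplotype], 0.02, pos=5000)
        after = score_read(observations + [extra], make_phase_set())
        assert after.lr_by_haplotype[before.best_haplotype] >= \
            before.lr_by_haplotype[before.best_haplotype] - 1e-9
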