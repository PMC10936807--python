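"""Multinomial scoring model for read-to-haplotype assignment.

A read overlapping n phased heterozygous SNVs is compared against each
haplotype h_i of the phase set. A base matching h_i's allele is a true
match with probability (1 - e), a mismatching base a true mismatch with
probability e/3 (three possible wrong nucleotides), where e is either the
per-base error from the Phred quality or a global mean error rate
epsilon. The per-haplotype probability is multinomial:

    P_hi = n! / (k_nm! * k_m!) * (eps/3)^k_nm * (1 - eps)^k_m

with k_m matches and k_nm = n - k_m mismatches. Posteriors use a uniform
prior 1/l over the l haplotypes; both the posterior and the likelihood
ratio divide each haplotype's term by the sum of the *other* haplotypes'
terms (an odds-like form: for diploids the resulting log10 LR of the best
haplotype is exactly twice the raw log10 probability ratio). All
arithmetic is done in log10 space with log-sum-exp; factorials via
log-gamma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from lrtag.variants import PhasedVariant, PhaseSet

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)
_ERR_FLOOR = 1e-12
_ERR_CEIL = 1.0 - 1e-12
TIE_TOL = 1e-9


@dataclass(frozen=True)
class ReadObservation:
    """The aligned read base and its error probability at one phased SNV."""

    variant: PhasedVariant
    observed_base: str
    base_error: float

    def matches(self, haplotype_index: int) -> bool:
        return self.observed_base == self.variant.alleles_by_haplotype[haplotype_index]

    @property
    def match_flags(self) -> tuple[tuple[int, int], ...]:
        """Per-haplotype indicator pair (x, y): x=1 on match, y=1 on mismatch."""
        return tuple((1, 0) if self.matches(i) else (0, 1)
                     for i in range(self.variant.ploidy))


@dataclass
class HaplotagScore:
    """Per-haplotype log10 probabilities, posteriors and likelihood ratios."""

    log10_prob_by_haplotype: list[float]
    posterior_by_haplotype: list[float]
    lr_by_haplotype: list[float]
    best_haplotype: int
    llr: float
    n_variants: int
    n_matches_best: int
    n_mismatches_best: int
    mean_epsilon_used: float
    tie: bool


def per_base_error(q: float) -> float:
    """Error probability for a Phred quality q: 10^(-0.1 q), capped at 1."""
    if q < 0:
        raise ValueError(f"Phred quality must be non-negative, got {q}")
    return min(10.0 ** (-0.1 * q), 1.0)


def _clamp_error(e: float) -> float:
    if e >= 1.0:
        logger.debug("base error %.3g clamped below 1 (q=0 base carries no information)", e)
    return min(max(e, _ERR_FLOOR), _ERR_CEIL)


def log10_multinomial_coeff(k_m: int, k_nm: int) -> float:
    n = k_m + k_nm
    return (gammaln(n + 1) - gammaln(k_m + 1) - gammaln(k_nm + 1)) / _LN10


def multinomial_prob_global(k_m: int, k_nm: int, epsilon: float,
                            use_coefficient: bool = True) -> float:
    """Multinomial probability of k_m matches and k_nm mismatches at a
    constant error rate epsilon (linear scale)."""
    return 10.0 ** log10_multinomial_prob_global(k_m, k_nm, epsilon, use_coefficient)


def log10_multinomial_prob_global(k_m: int, k_nm: int, epsilon: float,
                                  use_coefficient: bool = True) -> float:
    if k_m < 0 or k_nm < 0:
        raise ValueError("counts must be non-negative")
    if k_m + k_nm == 0:
        return 0.0
    if not (0.0 < epsilon < 1.0):
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    result = k_nm * math.log10(epsilon / 3.0) + k_m * math.log10(1.0 - epsilon)
    if use_coefficient:
        result += log10_multinomial_coeff(k_m, k_nm)
    return result


def log10_multinomial_prob(observations: Sequence[ReadObservation],
                           haplotype_index: int,
                           use_coefficient: bool = True) -> float:
    """Per-base generalization: sum over sites of log10(1-e) on a match and
    log10(e/3) on a mismatch, plus the multinomial coefficient."""
    total = 0.0
    k_m = 0
    for obs in observations:
        e = _clamp_error(obs.base_error)
        if obs.matches(haplotype_index):
            total += math.log10(1.0 - e)
            k_m += 1
        else:
            total += math.log10(e / 3.0)
    if use_coefficient and observations:
        total += log10_multinomial_coeff(k_m, len(observations) - k_m)
    return total


def uniform_prior(ploidy: int) -> float:
    """Uniform prior 1/l over haplotypes (equal a-priori probability)."""
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    return 1.0 / ploidy


def _log10sumexp(values: np.ndarray) -> float:
    return float(logsumexp(values * _LN10) / _LN10)


def _odds_transform(log10_terms: Sequence[float]) -> list[float]:
    """log10 of term_i / sum_{j != i} term_j, the shared structure of the
    posterior and likelihood-ratio formulas."""
    terms = np.asarray(log10_terms, dtype=float)
    if terms.size < 2:
        raise ValueError("need at least two haplotypes (denominator vanishes)")
    out = []
    for i in range(terms.size):
        others = np.delete(terms, i)
        out.append(float(terms[i] - _log10sumexp(others)))
    return out


def posterior(log10_probs: Sequence[float], priors: Sequence[float]) -> list[float]:
    """log10 posteriors: P_hi*b_hi over the summed terms of the other
    haplotypes (log-sum-exp over j != i)."""
    if len(log10_probs) != len(priors):
        raise ValueError("log10_probs and priors must have equal length")
    weighted = [lp + math.log10(b) for lp, b in zip(log10_probs, priors)]
    return _odds_transform(weighted)


def likelihood_ratio(log10_posteriors: Sequence[float]) -> list[float]:
    """log10 likelihood ratios: posterior_i over the summed posteriors of
    the other haplotypes."""
    return _odds_transform(log10_posteriors)


def score_read(observations: Sequence[ReadObservation],
               phase_set: PhaseSet,
               epsilon_global: float | None = None,
               use_coefficient: bool = True,
               per_base_mode: bool = True,
               tie_tol: float = TIE_TOL) -> HaplotagScore:
    """Score a read against every haplotype of one phase set.

    With ``per_base_mode`` the per-base error of each observation is used;
    otherwise the global epsilon enters a match/mismatch-count multinomial.
    The best haplotype is the argmax of the log10 likelihood ratios; a tie
    is flagged when two or more haplotypes come within ``tie_tol``.
    """
    if not observations:
        raise ValueError("cannot score a read with no observations (untaggable upstream)")
    ploidy = phase_set.ploidy
    n = len(observations)
    log10_probs = []
    k_m_by_hap = []
    for i in range(ploidy):
        k_m = sum(1 for obs in observations if obs.matches(i))
        k_m_by_hap.append(k_m)
        if per_base_mode:
            log10_probs.append(log10_multinomial_prob(observations, i, use_coefficient))
        else:
            if epsilon_global is None:
                raise ValueError("epsilon_global required when per_base_mode is off")
            log10_probs.append(
                log10_multinomial_prob_global(k_m, n - k_m, epsilon_global, use_coefficient))
    priors = [uniform_prior(ploidy)] * ploidy
    posteriors = posterior(log10_probs, priors)
    lrs = likelihood_ratio(posteriors)
    best = int(np.argmax(lrs))
    llr = lrs[best]
    tie = sum(1 for lr in lrs if lr >= llr - tie_tol) >= 2
    if per_base_mode:
        mean_eps = float(np.mean([_clamp_error(o.base_error) for o in observations]))
    else:
        mean_eps = float(epsilon_global)
    return HaplotagScore(
        log10_prob_by_haplotype=log10_probs,
        posterior_by_haplotype=posteriors,
        lr_by_haplotype=lrs,
        best_haplotype=best,
        llr=llr,
        n_variants=n,
        n_matches_best=k_m_by_hap[best],
        n_mismatches_best=n - k_m_by_hap[best],
        mean_epsilon_used=mean_eps,
        tie=tie,
    )
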