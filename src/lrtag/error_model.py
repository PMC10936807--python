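"""Post-hoc haplotagging error model (empirical FDR control).

Sequencing errors make the base at a het site uninformative; because
there are three possible wrong nucleotides, each site contributes eps/3
to the expected mistag rate. Treating per-read tagging as Bernoulli
trials with success probability 1 - eps/3 (conservatively ignoring the
number of sites per read), the number of mistags among N phaseable reads
follows a negative-binomial-style error distribution whose mean,
N * eps/3, estimates the expected error count. To enforce a target FDR
the floor(mean * (1 - fdr)) lowest-LLR tagged reads are relabeled
untagged.

``mean_mode='eps'`` exposes the alternative reading N * eps of the
expected-error mean for sensitivity analysis; the default is the eps/3
reading consistent with the per-read error rate above.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, TYPE_CHECKING

import numpy as np

from lrtag.scoring import per_base_error

if TYPE_CHECKING:
    from lrtag.engine import TagDecision

logger = logging.getLogger(__name__)


@dataclass
class ErrorModelConfig:
    """FDR-filter settings. ``fdr=0`` disables the filter entirely."""

    fdr: float = 0.0
    epsilon_source: str = "empirical"  # or "user-global"
    epsilon_value: float | None = None
    mean_mode: str = "eps3"  # expected errors = N*eps/3 ("eps3") or N*eps ("eps")

    def __post_init__(self):
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")
        if self.mean_mode not in ("eps3", "eps"):
            raise ValueError(f"unknown mean_mode {self.mean_mode!r}")


@dataclass
class FdrFilterReport:
    n_phaseable: int
    epsilon: float
    expected_errors: float
    n_relabeled: int


def estimate_epsilon(reads: Iterable) -> float:
    """Mean per-read sequencing error rate over a BAM record stream.

    Uses each record's ``de`` tag (aligner-reported gap-compressed
    divergence); records lacking the tag are skipped and counted. If no
    record carries ``de``, falls back to the mean per-base error implied
    by the quality strings.
    """
    de_values = []
    fallback_means = []
    n_missing = 0
    n_reads = 0
    for read in reads:
        n_reads += 1
        if read.has_tag("de"):
            de_values.append(float(read.get_tag("de")))
        else:
            n_missing += 1
            quals = read.query_qualities
            if quals is not None and len(quals) > 0:
                fallback_means.append(float(np.mean([per_base_error(q) for q in quals])))
    if n_reads == 0:
        raise ValueError("cannot estimate epsilon from an empty read stream")
    if de_values:
        if n_missing:
            logger.warning("estimate_epsilon: %d/%d reads lacked the 'de' tag and were skipped",
                           n_missing, n_reads)
        return float(np.mean(de_values))
    if fallback_means:
        logger.warning("estimate_epsilon: no 'de' tags found; falling back to mean "
                       "per-base error from quality strings (%d reads)", len(fallback_means))
        return float(np.mean(fallback_means))
    raise ValueError("no usable error-rate information in the BAM (no 'de' tags, no "
                     "base qualities); pass a global error rate via --epsilon")


def expected_error_count(n_phaseable: int, epsilon: float, mean_mode: str = "eps3") -> float:
    """Expected number of mistagged reads among ``n_phaseable`` reads."""
    if n_phaseable < 0:
        raise ValueError("n_phaseable must be >= 0")
    per_read = epsilon / 3.0 if mean_mode == "eps3" else epsilon
    return n_phaseable * per_read


def apply_fdr_filter(decisions: "Iterable[TagDecision]", fdr: float, epsilon: float,
                     mean_mode: str = "eps3") -> FdrFilterReport:
    """Relabel the k lowest-LLR tagged reads as untagged, in place.

    k = floor(expected_errors * (1 - fdr)) with N = phaseable reads (tagged
    plus untagged; untaggable reads carry no information and are never
    touched). Ties at the cut are broken by read name for determinism.
    ``fdr=0`` is the disable sentinel: the decision set is returned
    unchanged.
    """
    decisions = list(decisions)
    phaseable = [d for d in decisions if d.label in ("tagged", "untagged")]
    n_phaseable = len(phaseable)
    if fdr == 0.0:
        return FdrFilterReport(n_phaseable, epsilon, 0.0, 0)
    if not (0.0 < fdr <= 1.0):
        raise ValueError(f"fdr must lie in [0, 1], got {fdr}")
    expected = expected_error_count(n_phaseable, epsilon, mean_mode)
    k = math.floor(expected * (1.0 - fdr))
    tagged = sorted((d for d in decisions if d.label == "tagged"),
                    key=lambda d: (d.score.llr, d.read_name))
    if k >= len(tagged):
        logger.warning("apply_fdr_filter: expected errors (%d) >= tagged reads (%d); "
                       "relabeling all tagged reads", k, len(tagged))
        k = len(tagged)
    for d in tagged[:k]:
        d.relabel_untagged(reason="fdr_filter")
    return FdrFilterReport(n_phaseable, epsilon, expected, k)
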