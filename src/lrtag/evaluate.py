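"""Evaluation of haplotagging output against simulated truth.

Category definitions (per read):

* TP -- phaseable read tagged with its true haplotype;
* FP -- phaseable read tagged with a wrong haplotype (or, symmetrically,
  a nonphasable read tagged at all -- counted but expected to be zero,
  since the engine never tags a read without het-site observations);
* TN -- nonphasable read labeled untaggable;
* FN -- phaseable read left without a haplotype (untagged or untaggable).

"Phaseable" means the read's alignment overlaps at least one phased het
SNV by coordinate. Derived rates: IHR = FP / phaseable (incorrect
haplotagging rate), FNR = FN / phaseable, recall = TP / phaseable.
Precision-recall curves sweep the LLR threshold over tagged reads;
PR-AUC is the trapezoid area over recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.stats import kruskal

logger = logging.getLogger(__name__)


@dataclass
class EvalCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    fp_nonphasable: int = 0
    pr_points: list[tuple[float, float, float]] = field(default_factory=list)
    pr_auc: float = float("nan")

    @property
    def n_phaseable(self) -> int:
        return self.tp + self.fp + self.fn

    @property
    def ihr(self) -> float:
        return self.fp / self.n_phaseable if self.n_phaseable else 0.0

    @property
    def fnr(self) -> float:
        return self.fn / self.n_phaseable if self.n_phaseable else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.n_phaseable if self.n_phaseable else 0.0

    @property
    def precision(self) -> float:
        tagged = self.tp + self.fp
        return self.tp / tagged if tagged else 0.0


def classify(label: str, haplotype: int | None, truth_haplotype: int,
             phaseable: bool) -> str:
    """Assign one read to TP / FP / TN / FN (total and mutually exclusive)."""
    if phaseable:
        if label == "tagged":
            return "TP" if haplotype == truth_haplotype else "FP"
        return "FN"
    return "TN" if label != "tagged" else "FP"


def pr_curve(scores: list[tuple[float, bool]],
             n_positives: int | None = None) -> tuple[list[tuple[float, float, float]], float]:
    """Precision-recall sweep over distinct LLR thresholds, descending.

    ``scores`` holds one (LLR, is_correct) pair per evaluated read (use
    -inf for reads never tagged). ``n_positives`` is the recall
    denominator, defaulting to the number of entries. Returns the list of
    (recall, precision, threshold) points and the trapezoid PR-AUC.
    """
    if not scores:
        raise ValueError("pr_curve requires at least one scored read")
    n_positives = n_positives if n_positives is not None else len(scores)
    if n_positives < 1:
        raise ValueError("need at least one positive")
    arr = sorted(scores, key=lambda t: (-t[0], not t[1]))
    llrs = np.array([t[0] for t in arr])
    correct = np.array([t[1] for t in arr], dtype=float)
    cum_correct = np.cumsum(correct)
    cum_pred = np.arange(1, len(arr) + 1, dtype=float)
    # evaluate at the last index of each distinct threshold
    distinct = np.nonzero(np.diff(llrs, append=-np.inf))[0]
    points = []
    for idx in distinct:
        if not np.isfinite(llrs[idx]):
            continue
        recall = cum_correct[idx] / n_positives
        precision = cum_correct[idx] / cum_pred[idx]
        points.append((float(recall), float(precision), float(llrs[idx])))
    if not points:  # nothing ever tagged
        return [], 0.0
    recalls = np.array([p[0] for p in points])
    precisions = np.array([p[1] for p in points])
    # anchor at recall 0 with the precision of the strictest threshold
    recalls = np.concatenate([[0.0], recalls])
    precisions = np.concatenate([[precisions[0]], precisions])
    auc = float(np.trapezoid(precisions, recalls))
    return points, auc


def llr_rank_test(correct_llrs: np.ndarray, incorrect_llrs: np.ndarray) -> float:
    """Kruskal-Wallis p-value for incorrect tags ranking lower in LLR."""
    if len(correct_llrs) == 0 or len(incorrect_llrs) == 0:
        raise ValueError("both groups must be non-empty")
    return float(kruskal(correct_llrs, incorrect_llrs).pvalue)


def load_truth(truth_tsv: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(truth_tsv, sep="\t")
    required = {"read_name", "haplotype"}
    if not required.issubset(truth.columns):
        raise ValueError(f"truth table must contain columns {sorted(required)}")
    return truth.set_index("read_name")


def _decisions_frame_from_bam(bam_path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            hp = read.get_tag("HP") if read.has_tag("HP") else None
            n_overlap = read.get_tag("XV") if read.has_tag("XV") else 0
            n_scored = read.get_tag("NV") if read.has_tag("NV") else 0
            llr = float(read.get_tag("LL")) if read.has_tag("LL") else float("-inf")
            if hp is not None:
                label = "tagged"
            elif n_scored > 0 or n_overlap > 0:
                label = "untagged" if n_scored > 0 else "untaggable"
            else:
                label = "untaggable"
            rows.append((read.query_name, label, hp, llr, n_overlap))
    return pd.DataFrame(rows, columns=["read_name", "label", "haplotype", "llr",
                                       "n_overlap"]).set_index("read_name")


def summarize_decisions(decisions: pd.DataFrame, truth: pd.DataFrame) -> EvalCounts:
    """Join per-read decisions with truth on read name and tabulate."""
    joined = decisions.join(truth, how="inner", rsuffix="_truth")
    if joined.empty:
        raise ValueError("no read names shared between tagged output and truth table")
    if len(joined) < len(decisions):
        logger.warning("%d decided reads had no truth entry and were ignored",
                       len(decisions) - len(joined))
    tp = fp = tn = fn = fp_nonphasable = 0
    scores: list[tuple[float, bool]] = []
    for row in joined.itertuples():
        phaseable = row.n_overlap > 0
        outcome = classify(row.label, row.haplotype, row.haplotype_truth, phaseable)
        if outcome == "TP":
            tp += 1
            scores.append((row.llr, True))
        elif outcome == "FP":
            fp += 1
            if not phaseable:
                fp_nonphasable += 1
            scores.append((row.llr, False))
        elif outcome == "TN":
            tn += 1
        else:
            fn += 1
            scores.append((float("-inf"), False))
    counts = EvalCounts(tp=tp, fp=fp, tn=tn, fn=fn, fp_nonphasable=fp_nonphasable)
    if counts.n_phaseable and tp:
        counts.pr_points, counts.pr_auc = pr_curve(scores, n_positives=counts.n_phaseable)
    return counts


def summarize(bam_tagged: str | Path, truth_tsv: str | Path,
              out_prefix: str | Path | None = None, plot: bool = False) -> EvalCounts:
    """Evaluate a tagged BAM against a truth table; optionally write a TSV
    report and a PR-curve plot."""
    decisions = _decisions_frame_from_bam(bam_tagged)
    truth = load_truth(truth_tsv)
    counts = summarize_decisions(decisions, truth)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        report = pd.DataFrame([{
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
            "phaseable": counts.n_phaseable, "ihr": counts.ihr, "fnr": counts.fnr,
            "recall": counts.recall, "precision": counts.precision,
            "pr_auc": counts.pr_auc,
        }])
        report.to_csv(f"{out_prefix}.eval.tsv", sep="\t", index=False)
        if plot and counts.pr_points:
            _plot_pr(counts, f"{out_prefix}.pr.png")
    return counts


def _plot_pr(counts: EvalCounts, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recalls = [p[0] for p in counts.pr_points]
    precisions = [p[1] for p in counts.pr_points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(recalls, precisions, marker=".", lw=1)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_title(f"PR-AUC = {counts.pr_auc:.6f}")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
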