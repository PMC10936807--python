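"""End-to-end haplotagging engine.

Iterates BAM records, intersects each primary mapped read with the phased
variant store, builds per-site observations by walking the CIGAR, scores
the read against every haplotype of the phase set, and labels it:

* ``tagged``     -- a unique best haplotype with LLR above the threshold;
* ``untagged``   -- phaseable but tied or below threshold (or removed by
                    the FDR filter);
* ``untaggable`` -- no usable observation at any het site.

Tagged records are written back to BAM with decision metadata: HP
(1-based haplotype), PS (phase set), LL (log10 LLR), NV (sites scored),
XV (het sites overlapped by coordinate), MC/MM (match/mismatch counts at
the chosen haplotype), EP (mean error rate used).
"""

from __future__ import annotations

import csv
import logging
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from lrtag.error_model import FdrFilterReport, apply_fdr_filter, estimate_epsilon
from lrtag.scoring import HaplotagScore, ReadObservation, per_base_error, score_read
from lrtag.variants import VariantStore, parse_phased_vcf

logger = logging.getLogger(__name__)

# CIGAR op codes consuming query / reference
_QUERY_OPS = {0, 1, 4, 7, 8}
_REF_OPS = {0, 2, 3, 7, 8}


@dataclass
class HaplotagConfig:
    epsilon: float | None = None          # None -> estimate from 'de' tags
    fdr: float = 0.0                      # 0 disables the error model
    llr_threshold: float = 0.0            # tag only if LLR strictly above
    use_coefficient: bool = True
    per_base_mode: bool = True
    mean_mode: str = "eps3"
    split_output: bool = False


@dataclass
class TagDecision:
    read_name: str
    label: str                            # tagged | untagged | untaggable
    haplotype: int | None = None          # 0-based index into the phase set
    score: HaplotagScore | None = None
    phase_set_id: int | None = None
    n_overlap_variants: int = 0           # het sites overlapped by coordinate
    note: str = ""

    def relabel_untagged(self, reason: str = "") -> None:
        if self.label != "tagged":
            raise ValueError("only tagged reads can be relabeled untagged")
        self.label = "untagged"
        self.haplotype = None
        self.note = reason


@dataclass
class HaplotagSummary:
    n_tagged: int
    n_untagged: int
    n_untaggable: int
    n_unmapped: int
    n_skipped: int                        # secondary/supplementary/duplicate
    epsilon: float
    fdr_report: FdrFilterReport | None
    output_paths: list[Path]
    summary_path: Path
    decisions: dict[str, TagDecision] = field(default_factory=dict)

    @property
    def n_processed(self) -> int:
        return self.n_tagged + self.n_untagged + self.n_untaggable


def intersect_read(read: pysam.AlignedSegment, store: VariantStore,
                   epsilon_global: float | None = None) -> list[ReadObservation]:
    """Observations at every phased het SNV covered by an aligned base.

    Walks the CIGAR once: deletions and reference skips spanning a variant
    yield no observation, insertions never create one. Per-base error comes
    from the record's quality string; when qualities are absent the global
    epsilon is used for every base.
    """
    if read.is_unmapped:
        return []
    variants = store.query_overlaps(read.reference_name, read.reference_start,
                                    read.reference_end)
    if not variants:
        return []
    seq = read.query_sequence
    quals = read.query_qualities
    observations: list[ReadObservation] = []
    vi = 0
    rpos = read.reference_start
    qpos = 0
    for op, length in read.cigartuples:
        consumes_ref = op in _REF_OPS
        consumes_query = op in _QUERY_OPS
        if consumes_ref and consumes_query:  # aligned block
            block_end = rpos + length
            while vi < len(variants) and variants[vi].pos0 < block_end:
                v = variants[vi]
                if v.pos0 >= rpos:
                    qoff = qpos + (v.pos0 - rpos)
                    if quals is not None:
                        e = per_base_error(quals[qoff])
                    elif epsilon_global is not None:
                        e = epsilon_global
                    else:
                        raise ValueError("read has no base qualities and no global "
                                         "epsilon was provided")
                    observations.append(ReadObservation(v, seq[qoff], e))
                vi += 1
        elif consumes_ref:  # deletion / ref skip: variants here get no observation
            block_end = rpos + length
            while vi < len(variants) and variants[vi].pos0 < block_end:
                vi += 1
        if consumes_ref:
            rpos += length
        if consumes_query:
            qpos += length
        if vi >= len(variants):
            break
    return observations


def haplotag_read(read: pysam.AlignedSegment, store: VariantStore,
                  config: HaplotagConfig) -> TagDecision:
    """Score one primary mapped read and decide its label.

    Reads spanning multiple phase sets are scored only within the phase set
    contributing the most observations (cross-phase-set likelihoods are not
    comparable); a tie between phase sets leaves the read untagged.
    """
    name = read.query_name
    if read.is_unmapped:
        return TagDecision(name, "untaggable", note="unmapped")
    n_overlap = len(store.query_overlaps(read.reference_name, read.reference_start,
                                         read.reference_end))
    observations = intersect_read(read, store, config.epsilon)
    if not observations:
        return TagDecision(name, "untaggable", n_overlap_variants=n_overlap)

    by_ps = Counter(obs.variant.phase_set_id for obs in observations)
    if len(by_ps) > 1:
        top = by_ps.most_common(2)
        if top[0][1] == top[1][1]:
            return TagDecision(name, "untagged", n_overlap_variants=n_overlap,
                               note="phase_set_tie")
        ps_id = top[0][0]
        observations = [o for o in observations if o.variant.phase_set_id == ps_id]
        logger.debug("read %s spans %d phase sets; scored within PS=%d",
                     name, len(by_ps), ps_id)
    else:
        ps_id = next(iter(by_ps))

    score = score_read(observations, store.phase_sets[ps_id],
                       epsilon_global=config.epsilon,
                       use_coefficient=config.use_coefficient,
                       per_base_mode=config.per_base_mode)
    decision = TagDecision(name, "untagged", score=score, phase_set_id=ps_id,
                           n_overlap_variants=n_overlap)
    if score.tie:
        decision.note = "tie"
    elif score.llr <= config.llr_threshold:
        decision.note = "below_threshold"
    else:
        decision.label = "tagged"
        decision.haplotype = score.best_haplotype
    return decision


def _set_decision_tags(rec: pysam.AlignedSegment, d: TagDecision, epsilon: float) -> None:
    rec.set_tag("XV", d.n_overlap_variants, "i")
    if d.score is not None:
        rec.set_tag("LL", float(d.score.llr), "f")
        rec.set_tag("NV", d.score.n_variants, "i")
        rec.set_tag("MC", d.score.n_matches_best, "i")
        rec.set_tag("MM", d.score.n_mismatches_best, "i")
        rec.set_tag("EP", float(d.score.mean_epsilon_used), "f")
    else:
        rec.set_tag("NV", 0, "i")
        rec.set_tag("EP", float(epsilon), "f")
    if d.label == "tagged":
        rec.set_tag("HP", d.haplotype + 1, "i")
        rec.set_tag("PS", d.phase_set_id, "i")


def run(bam_in: str | Path, vcf: str | Path, sample: str, out_dir: str | Path,
        ref: str | Path | None = None, prefix: str = "haplotagged",
        config: HaplotagConfig | None = None) -> HaplotagSummary:
    """Haplotag every read of a BAM against a phased VCF.

    Two passes: the first scores primary mapped reads (secondary,
    supplementary and duplicate records pass through untouched); after the
    optional FDR filter, the second pass writes every input record exactly
    once to the output BAM(s) with decision tags, plus a per-read TSV
    summary. Output is deterministic for a fixed input and config.
    """
    config = config or HaplotagConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    store = parse_phased_vcf(vcf, sample)

    with pysam.AlignmentFile(str(bam_in), "rb") as bam:
        missing = [c for c in store.contigs if c not in bam.references]
        if missing:
            logger.warning("contigs in VCF but not in BAM header (skipped): %s", missing)
        if config.epsilon is not None:
            epsilon = config.epsilon
        else:
            epsilon = estimate_epsilon(r for r in bam
                                       if not (r.is_secondary or r.is_supplementary))

    scoring_config = HaplotagConfig(**{**config.__dict__, "epsilon": epsilon})
    decisions: dict[str, TagDecision] = {}
    n_unmapped = n_skipped = 0
    with pysam.AlignmentFile(str(bam_in), "rb") as bam:
        for read in bam:
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                n_skipped += 1
                continue
            if read.is_unmapped:
                n_unmapped += 1
                continue
            decisions[read.query_name] = haplotag_read(read, store, scoring_config)

    fdr_report = None
    if config.fdr > 0:
        fdr_report = apply_fdr_filter(decisions.values(), config.fdr, epsilon,
                                      config.mean_mode)

    counts = Counter(d.label for d in decisions.values())
    out_paths: list[Path] = []
    with pysam.AlignmentFile(str(bam_in), "rb") as bam:
        if config.split_output:
            writers = {label: pysam.AlignmentFile(
                str(out_dir / f"{prefix}.{label}.bam"), "wb", template=bam)
                for label in ("tagged", "untagged", "untaggable")}
            out_paths = [Path(w.filename.decode()) for w in writers.values()]
        else:
            combined = pysam.AlignmentFile(str(out_dir / f"{prefix}.bam"), "wb", template=bam)
            writers = {label: combined for label in ("tagged", "untagged", "untaggable")}
            out_paths = [out_dir / f"{prefix}.bam"]
        try:
            for read in bam:
                if read.is_secondary or read.is_supplementary or read.is_duplicate \
                        or read.is_unmapped:
                    writers["untaggable"].write(read)
                    continue
                d = decisions[read.query_name]
                _set_decision_tags(read, d, epsilon)
                writers[d.label].write(read)
        finally:
            for w in set(writers.values()):
                w.close()

    summary_path = out_dir / f"{prefix}.summary.tsv"
    _write_summary(summary_path, decisions)

    summary = HaplotagSummary(
        n_tagged=counts.get("tagged", 0),
        n_untagged=counts.get("untagged", 0),
        n_untaggable=counts.get("untaggable", 0),
        n_unmapped=n_unmapped,
        n_skipped=n_skipped,
        epsilon=epsilon,
        fdr_report=fdr_report,
        output_paths=out_paths,
        summary_path=summary_path,
        decisions=decisions,
    )
    logger.info("haplotagged %d reads: %d tagged, %d untagged, %d untaggable "
                "(epsilon=%.4g)", summary.n_processed, summary.n_tagged,
                summary.n_untagged, summary.n_untaggable, epsilon)
    return summary


def _write_summary(path: Path, decisions: dict[str, TagDecision]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_name", "label", "haplotype", "phase_set", "llr",
                         "n_overlap", "n_scored", "n_match", "n_mismatch",
                         "epsilon", "note"])
        for name in sorted(decisions):
            d = decisions[name]
            s = d.score
            writer.writerow([
                name, d.label,
                d.haplotype + 1 if d.haplotype is not None else ".",
                d.phase_set_id if d.phase_set_id is not None else ".",
                f"{s.llr:.6g}" if s else ".",
                d.n_overlap_variants,
                s.n_variants if s else 0,
                s.n_matches_best if s else ".",
                s.n_mismatches_best if s else ".",
                f"{s.mean_epsilon_used:.6g}" if s else ".",
                d.note,
            ])


def map_fastq(fastq: str | Path, ref: str | Path, out_bam: str | Path | None = None,
              preset: str = "map-ont") -> Path:
    """Map a FASTQ with minimap2 and return a coordinate-sorted, indexed BAM.

    Convenience wrapper only; the core pipeline consumes pre-mapped BAMs.
    """
    if shutil.which("minimap2") is None:
        raise FileNotFoundError("minimap2 not found on PATH; install minimap2 or "
                                "provide a pre-mapped BAM")
    fastq = Path(fastq)
    out_bam = Path(out_bam) if out_bam else fastq.with_suffix(".bam")
    if fastq.stat().st_size == 0:
        logger.warning("map_fastq: %s is empty; writing an empty BAM", fastq)
    with tempfile.NamedTemporaryFile(suffix=".sam", delete=False) as tmp:
        sam_path = tmp.name
    try:
        with open(sam_path, "wb") as sam_fh:
            subprocess.run(["minimap2", "-ax", preset, str(ref), str(fastq)],
                           stdout=sam_fh, stderr=subprocess.PIPE, check=True)
        pysam.sort("--no-PG", "-o", str(out_bam), sam_path)
        pysam.index(str(out_bam))
    finally:
        Path(sam_path).unlink(missing_ok=True)
    return out_bam
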