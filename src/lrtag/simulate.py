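"""Truth-labeled diploid long-read simulator.

Generates, fully in memory and deterministically under a seed:

* a uniform-random reference contig;
* phased heterozygous SNVs at a human-like density (one phase set per
  contig), written as a bgzipped, indexed VCF;
* two haplotype consensus sequences (SNV-only, so coordinates are shared
  with the reference);
* error-bearing long reads drawn from each haplotype, emitted directly
  as a coordinate-sorted, indexed BAM whose CIGARs come from the
  error-injection trace, with the truth haplotype and origin coordinates
  encoded in each read name, plus a plain-text truth table.

Read lengths follow a gamma distribution moment-matched to (mean, sd)
and truncated to [min, max]; per-read accuracy follows a truncated
normal; errors are placed uniformly along the read with substitution /
insertion / deletion proportions 23:31:46 by default, emulating nanopore
R10.4-class data. Base qualities are set to the Phred equivalent of each
read's realized error rate, and the realized rate is written to the
``de`` tag so downstream error-rate estimation is exercised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from scipy.stats import truncnorm

from lrtag.variants import parse_phased_vcf

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TRUTH_NAME_SEP = "!"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic diploid dataset.

    Read-length and accuracy defaults emulate a MinION R10.4-class run:
    mean length 25 kb (sd 20 kb, range 100 bp - 1 Mb), mean per-read
    accuracy 0.98 on [0.01, 1.0], error-type ratio substitution:
    insertion:deletion = 23:31:46. ``read_depth`` is fold coverage per
    haplotype. ``het_snv_rate`` defaults to ~1/1500 bp, approximating
    human heterozygous SNV density (a few million het sites per genome).
    """

    genome_length: int = 1_000_000
    het_snv_rate: float = 1.0 / 1500.0
    read_depth: float = 1.0
    length_mean: float = 25_000.0
    length_sd: float = 20_000.0
    length_min: int = 100
    length_max: int = 1_000_000
    accuracy_mean: float = 0.98
    accuracy_sd: float = 0.02
    accuracy_min: float = 0.01
    accuracy_max: float = 1.00
    error_ratio: tuple[int, int, int] = (23, 31, 46)
    seed: int = 0
    chrom: str = "chr1"
    sample: str = "SIM"

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.het_snv_rate <= 0:
            raise ValueError("het_snv_rate must be positive")
        if self.het_snv_rate * self.genome_length < 1:
            raise ValueError("expected variant count below 1; enlarge the genome or rate")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if not (0 < self.length_min <= self.length_max):
            raise ValueError("invalid read-length bounds")
        if not (0 < self.accuracy_min <= self.accuracy_max <= 1):
            raise ValueError("invalid accuracy bounds")
        if len(self.error_ratio) != 3 or any(r < 0 for r in self.error_ratio) \
                or sum(self.error_ratio) == 0:
            raise ValueError("error_ratio must be three non-negative integers")


@dataclass
class SimOutput:
    reference_fasta: Path
    vcf: Path
    bam: Path
    truth_tsv: Path
    n_variants: int
    n_reads: int
    config: SimulationConfig = field(repr=False, default=None)


def encode_truth_name(haplotype: int, chrom: str, start: int, end: int, serial: int) -> str:
    """Read name carrying the truth: 1-based haplotype, contig, 0-based
    half-open origin coordinates, serial number."""
    return TRUTH_NAME_SEP.join(["sim", f"h{haplotype}", chrom, str(start), str(end),
                                str(serial)])


def decode_truth_name(name: str) -> tuple[int, str, int, int, int]:
    parts = name.split(TRUTH_NAME_SEP)
    if len(parts) != 6 or parts[0] != "sim" or not parts[1].startswith("h"):
        raise ValueError(f"not a simulator truth name: {name!r}")
    return int(parts[1][1:]), parts[2], int(parts[3]), int(parts[4]), int(parts[5])


def _write_fasta(path: Path, chrom: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    pysam.faidx(str(path))


def generate_truth_genome(config: SimulationConfig, out_dir: str | Path,
                          rng: np.random.Generator | None = None) -> tuple[Path, Path]:
    """Random reference plus phased het SNVs; returns (FASTA, VCF) paths.

    Variant count is Poisson around genome_length * het_snv_rate; positions
    are sampled without collision; each site gets a random non-reference
    alternate allele and a random phase orientation (0|1 or 1|0). All
    variants share one phase set per contig.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = config.genome_length

    codes = rng.integers(0, 4, size=L, dtype=np.uint8)
    seq = _BASES[codes].tobytes().decode()

    n_var = int(rng.poisson(L * config.het_snv_rate))
    n_var = max(1, min(n_var, L))
    positions = np.sort(rng.choice(L, size=n_var, replace=False))
    alt_offsets = rng.integers(1, 4, size=n_var)          # shift within {1,2,3}
    swap = rng.random(n_var) < 0.5                        # which haplotype carries ALT

    fasta_path = out_dir / "reference.fa"
    _write_fasta(fasta_path, config.chrom, seq)

    vcf_plain = out_dir / "variants.vcf"
    with open(vcf_plain, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write(f"##contig=<ID={config.chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(_PS_HEADER_LINE + "\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{config.sample}\n")
        for pos, off, sw in zip(positions, alt_offsets, swap):
            ref_code = codes[pos]
            alt_code = (ref_code + off) % 4
            ref_b = chr(_BASES[ref_code])
            alt_b = chr(_BASES[alt_code])
            gt = "1|0" if sw else "0|1"
            fh.write(f"{config.chrom}\t{pos + 1}\t.\t{ref_b}\t{alt_b}\t.\tPASS\t.\t"
                     f"GT:PS\t{gt}:1\n")
    vcf_path = Path(pysam.tabix_index(str(vcf_plain), preset="vcf", force=True))
    logger.info("simulated genome: %d bp, %d het SNVs", L, n_var)
    return fasta_path, vcf_path


_PS_HEADER_LINE = '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">'


def build_haplotype_consensus(reference_fasta: str | Path, vcf: str | Path,
                              haplotype_index: int, sample: str = "SIM") -> str:
    """Apply one haplotype's alleles to the reference (SNV-only, so
    coordinates are preserved); returns the consensus sequence."""
    store = parse_phased_vcf(vcf, sample)
    with pysam.FastaFile(str(reference_fasta)) as fa:
        if len(fa.references) != 1:
            raise ValueError("expected a single-contig reference")
        chrom = fa.references[0]
        seq = bytearray(fa.fetch(chrom).encode())
    for variant in store.query_overlaps(chrom, 0, len(seq)):
        seq[variant.pos0] = ord(variant.alleles_by_haplotype[haplotype_index])
    return seq.decode()


def mutate_read(template: str, error_rate: float, error_ratio: tuple[int, int, int],
                rng: np.random.Generator) -> tuple[str, list[tuple[int, int]], tuple[int, int, int]]:
    """Inject sequencing errors into a template sequence.

    Each template base errs independently with probability ``error_rate``;
    an erring position becomes a substitution, a single-base insertion
    (before the base) or a single-base deletion with probabilities
    proportional to ``error_ratio``. Returns the mutated query sequence,
    its CIGAR as (op, length) tuples against the template, and the
    (substitution, insertion, deletion) counts.
    """
    L = len(template)
    if L == 0:
        return "", [], (0, 0, 0)
    if error_rate <= 0:
        return template, [(0, L)], (0, 0, 0)
    err_pos = np.flatnonzero(rng.random(L) < error_rate)
    probs = np.asarray(error_ratio, dtype=float)
    probs /= probs.sum()
    kinds = rng.choice(3, size=err_pos.size, p=probs)
    # random payloads drawn up front to keep the loop cheap
    sub_shift = rng.integers(1, 4, size=err_pos.size)
    ins_base = rng.integers(0, 4, size=err_pos.size)

    parts: list[str] = []
    cigar: list[tuple[int, int]] = []

    def emit(op: int, length: int) -> None:
        if length <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    prev = 0
    n_sub = n_ins = n_del = 0
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, pos in enumerate(err_pos):
        if pos > prev:
            parts.append(template[prev:pos])
            emit(0, pos - prev)
        kind = kinds[i]
        base = template[pos]
        if kind == 0:  # substitution
            code = (base_index.get(base, 0) + int(sub_shift[i])) % 4
            parts.append(chr(_BASES[code]))
            emit(0, 1)
            n_sub += 1
        elif kind == 1:  # insertion before the (kept) base
            parts.append(chr(_BASES[int(ins_base[i])]))
            parts.append(base)
            emit(1, 1)
            emit(0, 1)
            n_ins += 1
        else:  # deletion
            emit(2, 1)
            n_del += 1
        prev = pos + 1
    if prev < L:
        parts.append(template[prev:])
        emit(0, L - prev)
    return "".join(parts), cigar, (n_sub, n_ins, n_del)


def _draw_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Gamma moment-matched to (mean, sd), rejection-truncated to bounds."""
    shape = (config.length_mean / config.length_sd) ** 2
    scale = config.length_sd ** 2 / config.length_mean
    for _ in range(1000):
        ln = rng.gamma(shape, scale)
        if config.length_min <= ln <= config.length_max:
            return int(ln)
    return int(np.clip(config.length_mean, config.length_min, config.length_max))


def _draw_accuracy(config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.accuracy_sd == 0:
        return config.accuracy_mean
    a = (config.accuracy_min - config.accuracy_mean) / config.accuracy_sd
    b = (config.accuracy_max - config.accuracy_mean) / config.accuracy_sd
    return float(truncnorm.rvs(a, b, loc=config.accuracy_mean, scale=config.accuracy_sd,
                               random_state=rng))


def simulate_reads(config: SimulationConfig, consensus_by_haplotype: list[str],
                   out_dir: str | Path, rng: np.random.Generator | None = None,
                   emit_fastq: bool = False) -> tuple[Path, Path]:
    """Draw reads from each haplotype consensus up to the configured fold
    coverage and emit a coordinate-sorted, indexed BAM (coordinates and
    CIGARs come from the error-injection trace, so no aligner is needed)
    plus a truth TSV. Optionally also writes a FASTQ for true end-to-end
    runs through an external aligner."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    serial = 0
    for hap, consensus in enumerate(consensus_by_haplotype, start=1):
        L = len(consensus)
        target = config.read_depth * L
        covered = 0.0
        while covered < target:
            ln = _draw_length(config, rng)
            start = int(rng.integers(0, max(L - ln, 0) + 1))
            end = min(start + ln, L)
            template = consensus[start:end]
            accuracy = _draw_accuracy(config, rng)
            query, cigar, (n_sub, n_ins, n_del) = mutate_read(
                template, 1.0 - accuracy, config.error_ratio, rng)
            n_err = n_sub + n_ins + n_del
            rate = n_err / max(len(template), 1)
            q = 60 if rate <= 0 else int(np.clip(round(-10.0 * math.log10(rate)), 1, 60))
            serial += 1
            name = encode_truth_name(hap, config.chrom, start, end, serial)
            records.append((start, name, hap, end, query, cigar, q, rate))
            covered += end - start

    records.sort(key=lambda r: (r[0], r[1]))

    bam_path = out_dir / "simulated.bam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": config.chrom, "LN": config.genome_length}]}
    truth_path = out_dir / "truth.tsv"
    fastq_path = out_dir / "simulated.fastq"
    fastq_fh = open(fastq_path, "w") if emit_fastq else None
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam, \
            open(truth_path, "w") as truth_fh:
        truth_fh.write("read_name\thaplotype\tchrom\tstart\tend\n")
        for start, name, hap, end, query, cigar, q, rate in records:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = name
            rec.query_sequence = query
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigartuples = cigar
            rec.query_qualities = pysam.qualitystring_to_array(chr(q + 33) * len(query))
            rec.set_tag("de", float(rate), "f")
            bam.write(rec)
            truth_fh.write(f"{name}\t{hap}\t{config.chrom}\t{start}\t{end}\n")
            if fastq_fh is not None:
                fastq_fh.write(f"@{name}\n{query}\n+\n{chr(q + 33) * len(query)}\n")
    if fastq_fh is not None:
        fastq_fh.close()
    pysam.index(str(bam_path))
    logger.info("simulated %d reads (%.2fx per haplotype)", len(records), config.read_depth)
    return bam_path, truth_path


def simulate(config: SimulationConfig, out_dir: str | Path,
             emit_fastq: bool = False) -> SimOutput:
    """Full pipeline: truth genome, consensus haplotypes, reads, truth table."""
    config.validate()
    out_dir = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    fasta_path, vcf_path = generate_truth_genome(config, out_dir, rng)
    consensus = [build_haplotype_consensus(fasta_path, vcf_path, i, config.sample)
                 for i in range(2)]
    bam_path, truth_path = simulate_reads(config, consensus, out_dir, rng,
                                          emit_fastq=emit_fastq)
    store = parse_phased_vcf(vcf_path, config.sample)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        n_reads = bam.count(until_eof=True)
    return SimOutput(reference_fasta=fasta_path, vcf=vcf_path, bam=bam_path,
                     truth_tsv=truth_path, n_variants=len(store), n_reads=n_reads,
                     config=config)
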