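"""Shared fixtures: in-memory BAM record builders, a defective phased VCF
covering every repair category, and session-scoped simulations reused
across tests to keep the suite fast."""

from __future__ import annotations

import pysam
import pytest

from lrtag.engine import HaplotagConfig, run
from lrtag.evaluate import summarize
from lrtag.simulate import SimulationConfig, simulate
from lrtag.variants import PhasedVariant, PhaseSet, VariantStore


# ---------------------------------------------------------------- builders

def pv(pos: int, alleles: tuple[str, str] = ("A", "G"), ps: int = 1,
       chrom: str = "chr1") -> PhasedVariant:
    """1-based position; haplotype-1 allele is treated as REF."""
    return PhasedVariant(chrom=chrom, pos=pos, ref_allele=alleles[0],
                         alt_alleles=(alleles[1],), phase_set_id=ps,
                         alleles_by_haplotype=alleles)


def build_store(variants: list[PhasedVariant], sample: str = "S") -> VariantStore:
    store = VariantStore(sample)
    for v in variants:
        store.add(v, ploidy=v.ploidy)
    store.finalize()
    return store


def make_phase_set(ploidy: int = 2, ps_id: int = 1) -> PhaseSet:
    return PhaseSet(id=ps_id, sample="S", chrom="chr1", ploidy=ploidy)


BAM_HEADER = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 100_000}]}


def make_read(name: str = "read1", start: int = 0, seq: str = "ACGT" * 5,
              cigar: list[tuple[int, int]] | None = None, qual: int | None = 20,
              header: dict | None = None, **tags) -> pysam.AlignedSegment:
    hdr = pysam.AlignmentHeader.from_dict(header or BAM_HEADER)
    rec = pysam.AlignedSegment(hdr)
    rec.query_name = name
    rec.query_sequence = seq
    rec.flag = 0
    rec.reference_id = 0
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = cigar or [(0, len(seq))]
    if qual is not None:
        rec.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    for tag, value in tags.items():
        rec.set_tag(tag, value)
    return rec


# ------------------------------------------------------- defective VCF

DEFECTIVE_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##contig=<ID=chrX,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=String,Description="Phase set">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tINTEGRATION
chr1\t101\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:PATMAT
chr1\t201\t.\tC\tT\t.\tPASS\t.\tGT:PS:GQ\t1|0:PATMAT:50:EXTRA
chr1\t301\t.\tG\tGA\t.\tPASS\t.\tGT:PS\t0|1:PATMAT
chr1\t401\t.\tT\t<DEL>\t.\tPASS\t.\tGT:PS\t0|1:PATMAT
chrX\t501\t.\tA\tC\t.\tPASS\t.\tGT:PS\t0|1:PATMAT
chr1\t601\t.\tA\tG\t.\tPASS\t.\tGT:PS\t1/0:PATMAT
chr1\t701\t.\tA\tG\t.\tPASS\t.\tGT\t0|1
chr1\t801\t.\tC\tG\t.\tPASS\t.\tGT:PS\t1|1:PATMAT
"""


@pytest.fixture
def defective_vcf(tmp_path):
    path = tmp_path / "defective.vcf"
    path.write_text(DEFECTIVE_VCF)
    return path


# ------------------------------------------------ session-scoped simulations

@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Compact default-condition dataset: 1 Mb diploid genome, 2x/haplotype."""
    out_dir = tmp_path_factory.mktemp("small_sim")
    config = SimulationConfig(genome_length=1_000_000, read_depth=2.0, seed=7)
    return simulate(config, out_dir)


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    out_dir = tmp_path_factory.mktemp("small_run")
    summary = run(small_sim.bam, small_sim.vcf, "SIM", out_dir,
                  config=HaplotagConfig())
    return small_sim, summary


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """Desk-scale benchmark: 6 Mb diploid genome at human-like het density,
    5x per haplotype (>2000 phaseable reads), default read-length, accuracy
    and error-type conditions; error model off, LLR threshold 0."""
    out_dir = tmp_path_factory.mktemp("benchmark")
    config = SimulationConfig(genome_length=6_000_000, read_depth=5.0, seed=11)
    sim = simulate(config, out_dir / "sim")
    summary = run(sim.bam, sim.vcf, "SIM", out_dir / "tagged",
                  config=HaplotagConfig(fdr=0.0, llr_threshold=0.0))
    counts = summarize(summary.output_paths[0], sim.truth_tsv)
    return sim, summary, counts
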