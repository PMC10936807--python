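"""Phased-variant store: parse, validate, repair ("rescue"), index and query
phased heterozygous SNVs from VCF.

Haplotype identity is only meaningful within a *phase set*: a group of
variants phased relative to one another, identified by the ``PS`` FORMAT
tag. Internally all coordinates are 0-based half-open; VCF positions are
converted on ingest so that interval arithmetic matches BAM conventions.
"""

from __future__ import annotations

import gzip
import logging
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_SYMBOLIC_ALT = re.compile(r"[<>\[\]]")


@dataclass(frozen=True)
class PhasedVariant:
    """One heterozygous, phased SNV.

    ``alleles_by_haplotype`` lists the allele carried by each haplotype in
    phase-set order (index 0 = haplotype 1). All alleles are single
    nucleotides; ``pos`` keeps the original 1-based VCF coordinate and
    ``pos0`` the 0-based one used throughout the package.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    phase_set_id: int
    alleles_by_haplotype: tuple[str, ...]

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def ploidy(self) -> int:
        return len(self.alleles_by_haplotype)


@dataclass
class PhaseSet:
    """A group of co-phased variants for one sample on one contig."""

    id: int
    sample: str
    chrom: str
    ploidy: int
    variants: list[PhasedVariant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)


class VariantStore:
    """Indexed collection of phased het SNVs, queryable by genomic interval.

    Lookup is a binary search over per-contig position arrays (variants are
    points), giving O(log n + k) per query.
    """

    def __init__(self, sample: str):
        self.sample = sample
        self.phase_sets: dict[int, PhaseSet] = {}
        self._positions: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[PhasedVariant]] = {}
        self.excluded_counts: dict[str, int] = {}

    def add(self, variant: PhasedVariant, ploidy: int) -> None:
        ps = self.phase_sets.get(variant.phase_set_id)
        if ps is None:
            ps = PhaseSet(id=variant.phase_set_id, sample=self.sample,
                          chrom=variant.chrom, ploidy=ploidy)
            self.phase_sets[variant.phase_set_id] = ps
        if ps.chrom != variant.chrom:
            raise ValueError(
                f"phase set {variant.phase_set_id} spans contigs {ps.chrom} and {variant.chrom}")
        if ps.ploidy != ploidy:
            raise ValueError(f"inconsistent ploidy within phase set {variant.phase_set_id}")
        ps.variants.append(variant)
        self._by_chrom.setdefault(variant.chrom, []).append(variant)

    def finalize(self) -> None:
        for chrom, variants in self._by_chrom.items():
            variants.sort(key=lambda v: v.pos0)
            self._positions[chrom] = [v.pos0 for v in variants]
        for ps in self.phase_sets.values():
            ps.variants.sort(key=lambda v: v.pos0)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    @property
    def contigs(self) -> list[str]:
        return sorted(self._by_chrom)

    def query_overlaps(self, chrom: str, start: int, end: int) -> list[PhasedVariant]:
        """Variants whose 0-based position lies in [start, end), sorted."""
        if start > end:
            raise ValueError(f"query start {start} > end {end}")
        positions = self._positions.get(chrom)
        if not positions:
            return []
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end - 1)
        return self._by_chrom[chrom][lo:hi]


def _contig_number(chrom: str) -> int | None:
    """Numeric code for a contig: 1-22 for autosomes, 24/25/26 for X/Y/M."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    special = {"X": 24, "Y": 25, "M": 26, "MT": 26}
    if name.upper() in special:
        return special[name.upper()]
    if name.isdigit():
        return int(name)
    return None


def parse_phased_vcf(vcf_path: str | Path, sample: str) -> VariantStore:
    """Load phased heterozygous SNVs for one sample into a :class:`VariantStore`.

    Only records that are phased (``|`` separator), heterozygous (at least
    two distinct alleles in the genotype) and SNV at every carried allele
    are kept; everything else is excluded and tallied by category in
    ``store.excluded_counts``. Variants lacking a PS tag on a phased
    genotype are assigned a per-contig default phase set.
    """
    vcf = VCF(str(vcf_path))
    if sample not in vcf.samples:
        raise ValueError(
            f"sample {sample!r} not found in {vcf_path}; available samples: {vcf.samples}")
    sidx = vcf.samples.index(sample)

    store = VariantStore(sample)
    counts = {"unphased": 0, "homozygous": 0, "missing_genotype": 0, "not_snv": 0}
    n_defaulted_ps = 0
    default_ps: dict[str, int] = {}

    for rec in vcf:
        gt = rec.genotypes[sidx]
        allele_idx, phased = list(gt[:-1]), bool(gt[-1])
        if any(a is None or a < 0 for a in allele_idx):
            counts["missing_genotype"] += 1
            continue
        if not phased:
            counts["unphased"] += 1
            continue
        if len(set(allele_idx)) < 2:
            counts["homozygous"] += 1
            continue
        alleles = [rec.REF] + list(rec.ALT)
        carried = [alleles[a] for a in allele_idx]
        if len(rec.REF) != 1 or any(len(a) != 1 or _SYMBOLIC_ALT.search(a) for a in carried):
            counts["not_snv"] += 1
            continue
        ps_field = rec.format("PS")
        ps_value = None
        if ps_field is not None:
            raw = ps_field[sidx]
            if hasattr(raw, "item"):
                raw = raw.item() if raw.size == 1 else raw[0]
            if isinstance(raw, bytes):
                raw = raw.decode()
            try:
                ps_value = int(raw)
            except (TypeError, ValueError):
                ps_value = None
            if ps_value is not None and ps_value < 0:  # htslib missing sentinel
                ps_value = None
        if ps_value is None:
            key = rec.CHROM
            if key not in default_ps:
                # deterministic fallback id, disjoint from typical PS values
                num = _contig_number(key)
                default_ps[key] = -(num if num is not None else len(default_ps) + 100)
            ps_id = default_ps[key]
            n_defaulted_ps += 1
        else:
            ps_id = ps_value
        variant = PhasedVariant(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref_allele=rec.REF,
            alt_alleles=tuple(rec.ALT),
            phase_set_id=ps_id,
            alleles_by_haplotype=tuple(carried),
        )
        store.add(variant, ploidy=len(carried))

    store.excluded_counts = counts
    store.defaulted_ps_count = n_defaulted_ps
    if n_defaulted_ps:
        logger.info("parse_phased_vcf: %d phased records lacked PS; assigned "
                    "per-contig default phase sets", n_defaulted_ps)
    store.finalize()
    for category, n in counts.items():
        if n:
            logger.info("parse_phased_vcf: excluded %d records (%s)", n, category)
    if len(store) == 0:
        raise ValueError(f"{vcf_path} yields an empty store: no phased heterozygous SNVs "
                         f"for sample {sample!r}")
    return store


# --------------------------------------------------------------------------
# VCF rescue: repair a non-compliant phased VCF into VCF 4.3 form.
# --------------------------------------------------------------------------

@dataclass
class RescueReport:
    """Counts per repair category produced by :func:`rescue_vcf`."""

    records_in: int = 0
    snvs_kept: int = 0
    non_snv_dropped: int = 0
    ps_transliterated: int = 0
    extra_fields_removed: int = 0
    sample_header_renamed: int = 0
    fallback_contigs: list[str] = field(default_factory=list)
    ps_map: dict[tuple[str, str], int] = field(default_factory=dict)


def _open_text(path: str | Path):
    path = str(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_snv_record(ref: str, alts: list[str]) -> bool:
    if len(ref) != 1:
        return False
    for alt in alts:
        if alt in (".", "*"):
            continue
        if len(alt) != 1 or _SYMBOLIC_ALT.search(alt):
            return False
    return True


_OPS_HEADER = '##FORMAT=<ID=OPS,Number=1,Type=String,Description="Original phase set identifier">'
_PS_HEADER = '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">'


def rescue_vcf(vcf_in: str | Path, vcf_out: str | Path, sample_name: str) -> RescueReport:
    """Repair a spec-noncompliant phased VCF and write a VCF-4.3 file.

    Repairs applied, mirroring the defects seen in public benchmark call
    sets:

    1. string PS tags are transliterated to integers by concatenating the
       ordinal of first appearance of the PS string with a two-digit contig
       number (X/Y/M -> 24/25/26);
    2. the original PS string is preserved under a new FORMAT tag ``OPS``;
    3. a sample column header named ``INTEGRATION`` is replaced with
       ``sample_name``;
    4. genotype fields not declared in the FORMAT string are removed;
    5. indel and structural-variant records are dropped, SNVs kept.

    Contigs that cannot be mapped to a number fall back to a deterministic
    per-run index (recorded in the report).
    """
    report = RescueReport()
    ps_ordinal: dict[str, int] = {}
    fallback_contig_num: dict[str, int] = {}

    def contig_num(chrom: str) -> int:
        num = _contig_number(chrom)
        if num is not None:
            return num
        if chrom not in fallback_contig_num:
            fallback_contig_num[chrom] = 27 + len(fallback_contig_num)
            report.fallback_contigs.append(chrom)
            logger.warning("rescue_vcf: contig %r has no numeric code; using fallback %d",
                           chrom, fallback_contig_num[chrom])
        return fallback_contig_num[chrom]

    def transliterate(ps_string: str, chrom: str) -> int:
        if ps_string not in ps_ordinal:
            ps_ordinal[ps_string] = len(ps_ordinal) + 1
        value = int(f"{ps_ordinal[ps_string]}{contig_num(chrom):02d}")
        report.ps_map[(ps_string, chrom)] = value
        return value

    out_path = str(vcf_out)
    compress = out_path.endswith(".gz")
    write_path = out_path[:-3] if compress else out_path

    saw_ps_header = False
    with _open_text(vcf_in) as src, open(write_path, "wt") as dst:
        header_done = False
        for line in src:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if line.startswith("##fileformat"):
                    dst.write("##fileformat=VCFv4.3\n")
                elif "ID=PS" in line and line.startswith("##FORMAT"):
                    saw_ps_header = True
                    dst.write(_PS_HEADER + "\n")
                else:
                    dst.write(line + "\n")
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                for i in range(9, len(cols)):
                    if cols[i] == "INTEGRATION":
                        cols[i] = sample_name
                        report.sample_header_renamed += 1
                if not saw_ps_header:
                    dst.write(_PS_HEADER + "\n")
                dst.write(_OPS_HEADER + "\n")
                dst.write("\t".join(cols) + "\n")
                header_done = True
                continue
            if not header_done:
                dst.write(line + "\n")
                continue

            cols = line.split("\t")
            if len(cols) < 10:
                continue
            report.records_in += 1
            chrom, ref, alt = cols[0], cols[3], cols[4]
            if not _is_snv_record(ref, alt.split(",")):
                report.non_snv_dropped += 1
                continue
            fmt_keys = cols[8].split(":")
            ps_idx = fmt_keys.index("PS") if "PS" in fmt_keys else None
            add_ops = ps_idx is not None
            for i in range(9, len(cols)):
                fields = cols[i].split(":")
                if len(fields) > len(fmt_keys):
                    report.extra_fields_removed += len(fields) - len(fmt_keys)
                    fields = fields[: len(fmt_keys)]
                ops_value = "."
                if ps_idx is not None and ps_idx < len(fields):
                    ps_value = fields[ps_idx]
                    ops_value = ps_value
                    if ps_value not in (".", "") and not re.fullmatch(r"-?\d+", ps_value):
                        fields[ps_idx] = str(transliterate(ps_value, chrom))
                        report.ps_transliterated += 1
                if add_ops:
                    fields.append(ops_value)
                cols[i] = ":".join(fields)
            if add_ops:
                cols[8] = ":".join(fmt_keys + ["OPS"])
            report.snvs_kept += 1
            dst.write("\t".join(cols) + "\n")

    if compress:
        pysam.tabix_compress(write_path, out_path, force=True)
        Path(write_path).unlink()
        try:
            pysam.tabix_index(out_path, preset="vcf", force=True)
        except OSError:  # unsorted input cannot be indexed; still valid bgzip VCF
            logger.warning("rescue_vcf: could not tabix-index %s", out_path)
    return report
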