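"""VCF genotype-record filtering at fixed quality thresholds.

Implements the phasing-accuracy QC filter used for parental genotype calls on
a phased assembly: a record passes only if its site QUAL sits at the caller's
999 cap, every sample reaches the depth and genotype-quality floors (DP >= 20,
GQ >= 20 by default) and no genotype is missing (vcftools ``max-missing = 1``,
i.e. call rate 1.0 — exposed here as ``max_missing_fraction = 0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


class AlleleClass(str, Enum):
    """Diploid genotype classes used by the donor rules."""

    REF_HOMO = "ref_homo"
    HET = "het"
    ALT_HOMO = "alt_homo"
    MISSING = "missing"


@dataclass(frozen=True)
class SampleCall:
    gt: str  # raw VCF GT field, e.g. "0/1"
    dp: int | None
    gq: int | None


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site with QUAL and per-sample GT/DP/GQ (position is 1-based)."""

    scaffold_id: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    samples: dict[str, SampleCall]

    def allele_class(self, sample: str) -> AlleleClass:
        return classify_genotype(self.samples[sample].gt, record=self)


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults reproduce the study setting: QUAL=999, DP>=20, GQ>=20, max-missing=1."""

    qual_min: float = 999.0
    dp_min: int = 20
    gq_min: int = 20
    max_missing_fraction: float = 0.0


@dataclass
class FilterStats:
    """Per-criterion failure counts (a record may fail several criteria)."""

    n_input: int = 0
    n_pass: int = 0
    fail_qual: int = 0
    fail_dp: int = 0
    fail_gq: int = 0
    fail_missing: int = 0
    fail_absent_format: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def classify_genotype(gt_field: str, ref: str | None = None, alts=None, record=None) -> AlleleClass:
    """Map a diploid GT string onto an allele class.

    0/0 -> ref-homozygous; any pair containing two distinct alleles (including
    two different ALTs, e.g. 1/2) -> heterozygous; x/x with x > 0 ->
    alt-homozygous; ./. -> missing. Phased separators are treated as unphased.
    """
    gt = gt_field.replace("|", "/")
    parts = gt.split("/")
    if len(parts) != 2:
        where = f" in record {record.scaffold_id}:{record.position}" if record else ""
        raise ValueError(f"non-diploid GT field {gt_field!r}{where}")
    if parts[0] == "." or parts[1] == ".":
        return AlleleClass.MISSING
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"unparseable GT field {gt_field!r}") from exc
    if a == b:
        return AlleleClass.REF_HOMO if a == 0 else AlleleClass.ALT_HOMO
    return AlleleClass.HET


def record_passes(record: VariantRecord, thresholds: FilterThresholds, stats: FilterStats | None = None) -> bool:
    """Apply all four criteria; records lacking DP or GQ fail (counted)."""
    ok = True
    if record.qual is None or record.qual < thresholds.qual_min:
        ok = False
        if stats:
            stats.fail_qual += 1
    n_missing = 0
    dp_bad = gq_bad = absent = False
    for call in record.samples.values():
        if classify_genotype(call.gt, record=record) is AlleleClass.MISSING:
            n_missing += 1
            continue
        if call.dp is None or call.gq is None:
            absent = True
            continue
        if call.dp < thresholds.dp_min:
            dp_bad = True
        if call.gq < thresholds.gq_min:
            gq_bad = True
    if absent:
        ok = False
        if stats:
            stats.fail_absent_format += 1
    if dp_bad:
        ok = False
        if stats:
            stats.fail_dp += 1
    if gq_bad:
        ok = False
        if stats:
            stats.fail_gq += 1
    if record.samples and n_missing / len(record.samples) > thresholds.max_missing_fraction:
        ok = False
        if stats:
            stats.fail_missing += 1
    return ok


def filter_variants(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    stats: FilterStats | None = None,
) -> Iterator[VariantRecord]:
    """Yield passing records in input order."""
    for rec in records:
        if stats:
            stats.n_input += 1
        if record_passes(rec, thresholds, stats):
            if stats:
                stats.n_pass += 1
            yield rec


# ---------------------------------------------------------------------------
# VCF I/O (cyvcf2-backed)
# ---------------------------------------------------------------------------


def read_vcf(path) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF (plain or bgzipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    for v in vcf:
        dp = v.format("DP")
        gq = v.format("GQ")
        calls = {}
        for i, name in enumerate(samples):
            g = v.genotypes[i]
            alleles = g[:-1]
            gt = "/".join("." if a is None or a < 0 else str(a) for a in alleles)
            calls[name] = SampleCall(
                gt=gt,
                dp=None if dp is None or dp[i][0] < 0 else int(dp[i][0]),
                gq=None if gq is None or gq[i][0] < 0 else int(gq[i][0]),
            )
        yield VariantRecord(
            scaffold_id=v.CHROM,
            position=v.POS,
            ref_allele=v.REF,
            alt_alleles=tuple(v.ALT),
            qual=v.QUAL if v.QUAL is not None else float("-inf"),
            samples=calls,
        )


def vcf_scaffold_names(path) -> list[str]:
    from cyvcf2 import VCF

    return list(VCF(str(path)).seqnames)


def filter_vcf_file(in_path, out_path, thresholds: FilterThresholds = FilterThresholds()) -> FilterStats:
    """Filter a VCF on disk, preserving header and record text verbatim."""
    from cyvcf2 import VCF, Writer

    stats = FilterStats()
    vcf = VCF(str(in_path), gts012=False)
    writer = Writer(str(out_path), vcf)
    samples = list(vcf.samples)
    for v in vcf:
        stats.n_input += 1
        dp = v.format("DP")
        gq = v.format("GQ")
        calls = {}
        for i, name in enumerate(samples):
            alleles = v.genotypes[i][:-1]
            gt = "/".join("." if a is None or a < 0 else str(a) for a in alleles)
            calls[name] = SampleCall(
                gt=gt,
                dp=None if dp is None or dp[i][0] < 0 else int(dp[i][0]),
                gq=None if gq is None or gq[i][0] < 0 else int(gq[i][0]),
            )
        rec = VariantRecord(v.CHROM, v.POS, v.REF, tuple(v.ALT),
                            v.QUAL if v.QUAL is not None else float("-inf"), calls)
        if record_passes(rec, thresholds, stats):
            stats.n_pass += 1
            writer.write_record(v)
    writer.close()
    return stats
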