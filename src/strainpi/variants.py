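"""SNP/INDEL calling from pileups, VCF I/O and cross-sample support filters.

The caller is a deliberately simple frequency-threshold model: a
non-reference base at a site is a candidate SNP in a sample when it is
supported by at least ``min_alt_reads`` reads AND makes up at least
``min_alt_frac`` of the site's coverage.  Candidates are merged across
samples per (genome, position, alt allele).  No genotype likelihoods, base
quality or realignment are involved; externally produced VCFs (with
per-sample AD fields) are accepted through :func:`read_vcf` as an
alternative input path.

The retention filter keeps a variant when it is present in at least
``min_samples`` samples and supported by at least ``min_reads`` reads,
where the read threshold is applied either in every supporting sample
(``per_sample``, default) or to the total over samples
(``per_variant_total``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from strainpi.pileup_coverage import BASES, PileupMatrix

logger = logging.getLogger(__name__)

_VALID_SCOPES = ("per_sample", "per_variant_total")


@dataclass
class VariantRecord:
    genome: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str  # "SNP" or "INDEL"
    support: dict[str, int] = field(default_factory=dict)  # sample -> alt reads
    depth: dict[str, int] = field(default_factory=dict)  # sample -> total depth

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt allele equals ref")
        if self.variant_class == "SNP" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNP alleles must be single bases")
        if self.variant_class == "INDEL" and len(self.ref) == len(self.alt):
            raise ValueError("INDEL alleles must differ in length")
        for s, n in self.support.items():
            if s in self.depth and n > self.depth[s]:
                raise ValueError(f"support exceeds depth in sample {s}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.genome, self.pos, self.ref, self.alt)

    @property
    def n_samples_present(self) -> int:
        return sum(1 for n in self.support.values() if n >= 1)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass(frozen=True)
class FilterPolicy:
    min_samples: int = 2
    min_reads: int = 4
    reads_scope: str = "per_sample"

    def __post_init__(self) -> None:
        if self.min_samples < 1 or self.min_reads < 1:
            raise ValueError("thresholds must be >= 1")
        if self.reads_scope not in _VALID_SCOPES:
            raise ValueError(f"reads_scope must be one of {_VALID_SCOPES}")


def call_variants(
    pileups: Mapping[str, PileupMatrix],
    references: Mapping[str, str],
    min_alt_reads: int = 2,
    min_alt_frac: float = 0.1,
) -> list[VariantRecord]:
    """Call SNPs (and CIGAR-reported INDELs) from per-sample pileups.

    ``pileups`` maps sample id -> PileupMatrix; all pileups of the same
    genome id must share the reference in ``references``.  Returns records
    sorted by (genome, pos, alt) carrying per-sample support and depth.
    Sites whose reference base is not one of A/C/G/T are skipped (counted
    in a warning).
    """
    merged: dict[tuple[str, int, str, str], VariantRecord] = {}
    skipped_ref = 0
    base_idx = {b: i for i, b in enumerate(BASES)}
    for sample, pileup in pileups.items():
        genome = pileup.genome
        ref_seq = references[genome]
        counts = pileup.counts
        cov = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = counts / np.where(cov > 0, cov, 1)[:, None]
        cand = (counts >= min_alt_reads) & (frac >= min_alt_frac)
        for i, b in np.argwhere(cand):
            ref_base = ref_seq[i]
            if ref_base not in base_idx:
                skipped_ref += 1
                continue
            if b == base_idx[ref_base]:
                continue
            key = (genome, int(i) + 1, ref_base, BASES[b])
            rec = merged.get(key)
            if rec is None:
                rec = VariantRecord(genome, int(i) + 1, ref_base, BASES[b], "SNP")
                merged[key] = rec
            rec.support[sample] = int(counts[i, b])
            rec.depth[sample] = int(cov[i])
        # CIGAR-reported indels, same support threshold (no fraction gate:
        # indel-spanning coverage is not tracked per base)
        for pos, events in pileup.indels.items():
            for (ref_a, alt_a), n in events.items():
                if n < min_alt_reads:
                    continue
                key = (genome, pos, ref_a, alt_a)
                rec = merged.get(key)
                if rec is None:
                    rec = VariantRecord(genome, pos, ref_a, alt_a, "INDEL")
                    merged[key] = rec
                rec.support[sample] = n
                rec.depth[sample] = max(n, int(cov[pos - 1]))
    if skipped_ref:
        logger.warning("skipped %d candidate sites with non-ACGT reference base", skipped_ref)
    # fill zero-support depths for samples that covered the site
    for rec in merged.values():
        for sample, pileup in pileups.items():
            if pileup.genome == rec.genome and sample not in rec.depth:
                rec.depth[sample] = int(pileup.coverage[rec.pos - 1])
    return sorted(merged.values(), key=lambda r: r.key)


def filter_variants(records: Sequence[VariantRecord], policy: FilterPolicy) -> list[VariantRecord]:
    """Retain variants present in enough samples with enough read support."""
    out = []
    for rec in records:
        if rec.n_samples_present < policy.min_samples:
            continue
        if policy.reads_scope == "per_sample":
            ok = all(n >= policy.min_reads for n in rec.support.values() if n >= 1)
        else:
            ok = rec.total_support >= policy.min_reads
        if ok:
            out.append(rec)
    return out


def snp_density(records: Sequence[VariantRecord], genome_length: int, genome: str | None = None) -> float:
    """SNP-class records per 1,000 bases of the genome."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n = sum(
        1
        for r in records
        if r.variant_class == "SNP" and (genome is None or r.genome == genome)
    )
    return 1000.0 * n / genome_length


# ---------------------------------------------------------------------------
# VCF I/O (via pysam; AD carries per-sample alt read support)


def write_vcf(
    records: Sequence[VariantRecord],
    path,
    reference_lengths: Mapping[str, int],
    samples: Sequence[str] | None = None,
) -> None:
    if samples is None:
        seen: list[str] = []
        for rec in records:
            for s in list(rec.support) + list(rec.depth):
                if s not in seen:
                    seen.append(s)
        samples = seen
    header = pysam.VariantHeader()
    for genome, length in reference_lengths.items():
        header.contigs.add(genome, length=length)
    header.formats.add("AD", "R", "Integer", "Read depth per allele (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            site = vcf.new_record(
                contig=rec.genome,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            for s in samples:
                dp = rec.depth.get(s)
                alt_n = rec.support.get(s, 0)
                if dp is None:
                    site.samples[s]["AD"] = (None, None)
                else:
                    site.samples[s]["AD"] = (dp - alt_n, alt_n)
                    site.samples[s]["DP"] = dp
            vcf.write(site)


def read_vcf(path) -> list[VariantRecord]:
    """Read VCF records; multi-allelic sites split into biallelic records.

    Alt read support comes from the per-sample AD field; a sample with a
    missing AD contributes no support and no depth (such records fall out
    of read-count filters naturally).  Returns records sorted by key.
    """
    out: list[VariantRecord] = []
    missing_ad = 0
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            ref = site.ref
            for ai, alt in enumerate(site.alts or ()):
                vclass = "SNP" if len(ref) == 1 and len(alt) == 1 else "INDEL"
                rec = VariantRecord(site.contig, site.pos, ref, alt, vclass)
                for s in site.samples:
                    fmt = site.samples[s]
                    ad = fmt.get("AD")
                    if ad is None or all(v is None for v in ad):
                        missing_ad += 1
                        continue
                    alt_n = ad[ai + 1] if len(ad) > ai + 1 and ad[ai + 1] is not None else 0
                    dp = fmt.get("DP")
                    if dp is None:
                        dp = sum(v for v in ad if v is not None)
                    rec.depth[s] = int(dp)
                    if alt_n:
                        rec.support[s] = int(alt_n)
                out.append(rec)
    if missing_ad:
        logger.warning("%d sample genotypes lacked AD; excluded from read support", missing_ad)
    return sorted(out, key=lambda r: r.key)


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    columns = ["genome", "pos", "ref", "alt", "class", "n_samples", "total_support"]
    if not records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "genome": r.genome,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "class": r.variant_class,
                "n_samples": r.n_samples_present,
                "total_support": r.total_support,
            }
            for r in records
        ]
    )
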