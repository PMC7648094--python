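"""Quantify the effect of a decoy on alignment and variant genotypes.

Contaminant read pairs that co-opt a short reference k-mer pile up at a
locus, support the reference allele there, and can pull a true homozygous-
alternate genotype down to a false heterozygote. Adding a decoy contig
sequesters those reads; this module measures the consequences by

* counting variants called near atypical-alignment clusters,
* classifying per-locus genotype changes between a pre-decoy and post-decoy
  callset (``lost``, ``new``, ``restored_hom_alt``, ``unchanged``, ``other``),
* computing percent-reduction metrics for unaligned reads and atypical pairs,
* partitioning allelic support at a SNV between typically and atypically
  aligned reads.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from cyvcf2 import VCF

from .alignment_scan import AtypicalCluster

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentStats",
    "GenotypeChange",
    "AllelicSupport",
    "VariantRecord",
    "read_vcf_records",
    "variants_near_atypical",
    "compare_vcfs",
    "reduction_metrics",
    "allelic_support_partition",
    "fraction_variants_attributable",
]

CHANGE_CLASSES = ("lost", "new", "restored_hom_alt", "unchanged", "other")


@dataclass(frozen=True)
class AlignmentStats:
    """Read-level census of one alignment (pre- or post-decoy)."""

    n_reads_total: int
    n_unaligned: int
    n_atypical_pairs: int
    n_mapped_to_decoy: int = 0

    def __post_init__(self) -> None:
        if min(self.n_reads_total, self.n_unaligned, self.n_atypical_pairs,
               self.n_mapped_to_decoy) < 0:
            raise ValueError("alignment stats counts must be non-negative")


@dataclass(frozen=True)
class VariantRecord:
    """One decomposed (bi-allelic) variant: key + genotype + quality."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt: str   # "0/0", "0/1", "1/1", "./."
    qual: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeChange:
    chrom: str
    pos: int
    ref: str
    alt: str
    gt_pre: str | None
    gt_post: str | None
    qual_pre: float | None
    qual_post: float | None
    change_class: str


@dataclass(frozen=True)
class AllelicSupport:
    """Read support at one SNV, split typical/atypical x ref/alt."""

    chrom: str
    pos: int
    ref_support_typical: int
    alt_support_typical: int
    ref_support_atypical: int
    alt_support_atypical: int
    other_support: int = 0
    n_not_overlapping: int = 0


def read_vcf_records(path: str | Path, sample_index: int = 0) -> list[VariantRecord]:
    """Load a VCF into decomposed per-alt records.

    Multi-allelic sites are split into one record per alternate allele; the
    genotype is re-expressed against that single alt (alleles equal to the
    alt become 1, anything else 0, missing stays '.'). Records without a
    sample column get genotype './.'.
    """
    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    for var in vcf:
        gts = var.genotypes[sample_index] if len(var.genotypes) > sample_index else None
        for alt_idx, alt in enumerate(var.ALT, start=1):
            if gts is None:
                gt = "./."
            else:
                alleles = gts[:-1]
                mapped = [
                    "." if a < 0 else ("1" if a == alt_idx else "0") for a in alleles
                ]
                gt = "/".join(sorted(mapped))
            out.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    gt=gt,
                    qual=float(var.QUAL) if var.QUAL is not None else float("nan"),
                )
            )
    vcf.close()
    return out


def variants_near_atypical(
    variants: Sequence[VariantRecord] | str | Path,
    clusters: Sequence[AtypicalCluster],
    window: int = 100,
) -> list[VariantRecord]:
    """Variants within ``window`` bp (inclusive) of any atypical cluster.

    Distance is measured from the variant POS to the nearest base of the
    cluster interval; a variant inside a cluster is at distance 0. A complete
    contig-naming mismatch between the VCF and the clusters (no contig in
    common while both are non-empty) is a hard error listing the offenders,
    since it almost always means mixed chr-prefix conventions.
    """
    if isinstance(variants, (str, Path)):
        variants = read_vcf_records(variants)
    if not variants or not clusters:
        return []
    # per contig: starts sorted ascending with a running maximum of ends, so
    # "any interval with start <= pos+window and end >= pos-window" is one
    # bisect plus one lookup, valid for arbitrary (even overlapping) clusters
    by_ref: dict[str, tuple[list[int], list[int]]] = {}
    for ref in {c.ref_name for c in clusters}:
        ivs = sorted((c for c in clusters if c.ref_name == ref), key=lambda c: c.start)
        starts = [c.start for c in ivs]
        max_end = []
        cur = -(10**18)
        for c in ivs:
            cur = max(cur, c.end)
            max_end.append(cur)
        by_ref[ref] = (starts, max_end)

    var_contigs = {v.chrom for v in variants}
    if not (var_contigs & set(by_ref)):
        raise ValueError(
            "no contig in common between variants and clusters: "
            f"VCF has {sorted(var_contigs)}, clusters have {sorted(by_ref)}"
        )

    out: list[VariantRecord] = []
    for v in variants:
        idx = by_ref.get(v.chrom)
        if idx is None:
            continue
        starts, max_end = idx
        i = bisect_right(starts, v.pos + window) - 1
        if i >= 0 and max_end[i] >= v.pos - window:
            out.append(v)
    return out


def _classify(gt_pre: str | None, gt_post: str | None) -> str:
    if gt_pre is not None and gt_post is None:
        return "lost"
    if gt_pre is None and gt_post is not None:
        return "new"
    if gt_pre == gt_post:
        return "unchanged"
    if gt_pre == "0/1" and gt_post == "1/1":
        return "restored_hom_alt"
    return "other"


def compare_vcfs(
    vcf_pre: str | Path | Sequence[VariantRecord],
    vcf_post: str | Path | Sequence[VariantRecord],
) -> tuple[list[GenotypeChange], dict]:
    """Classify per-locus genotype changes between two callsets.

    Loci are matched on (chrom, pos, ref, alt) after multi-allelic
    decomposition; both callsets are assumed to come from the same caller
    pipeline, so no left-normalisation is applied. The classification is a
    partition: every locus present in either callset gets exactly one class.
    The summary carries per-class counts and the median QUAL of lost variants
    (lower-median for even counts, so the value is always an observed QUAL).
    """
    pre = read_vcf_records(vcf_pre) if isinstance(vcf_pre, (str, Path)) else list(vcf_pre)
    post = read_vcf_records(vcf_post) if isinstance(vcf_post, (str, Path)) else list(vcf_post)
    pre_by_key: dict = {v.key: v for v in pre}
    post_by_key: dict = {v.key: v for v in post}

    changes: list[GenotypeChange] = []
    for key in sorted(set(pre_by_key) | set(post_by_key)):
        vp = pre_by_key.get(key)
        vq = post_by_key.get(key)
        changes.append(
            GenotypeChange(
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                gt_pre=vp.gt if vp else None,
                gt_post=vq.gt if vq else None,
                qual_pre=vp.qual if vp else None,
                qual_post=vq.qual if vq else None,
                change_class=_classify(vp.gt if vp else None, vq.gt if vq else None),
            )
        )

    counts = {cls: 0 for cls in CHANGE_CLASSES}
    for ch in changes:
        counts[ch.change_class] += 1
    lost_quals = sorted(
        ch.qual_pre for ch in changes if ch.change_class == "lost" and ch.qual_pre is not None
    )
    median_lost = lost_quals[(len(lost_quals) - 1) // 2] if lost_quals else None
    summary = {
        "counts": counts,
        "n_pre": len(pre_by_key),
        "n_post": len(post_by_key),
        "median_qual_lost": median_lost,
    }
    return changes, summary


def reduction_metrics(
    stats_pre: AlignmentStats,
    stats_post: AlignmentStats,
) -> dict[str, float | None]:
    """Percent reduction, pre vs post decoy: 100 x (1 - post/pre).

    Computed for the unaligned-read count and the atypical-pair count. A zero
    pre-count makes the metric undefined (``None``), never 0 or infinity; a
    post-count exceeding pre yields a negative value with a warning rather
    than clamping.
    """
    out: dict[str, float | None] = {}
    for name, pre, post in (
        ("pct_reduction_unaligned", stats_pre.n_unaligned, stats_post.n_unaligned),
        ("pct_reduction_atypical", stats_pre.n_atypical_pairs, stats_post.n_atypical_pairs),
    ):
        if pre == 0:
            out[name] = None
            continue
        r = 100.0 * (1.0 - post / pre)
        if r < 0:
            logger.warning("%s negative (%0.2f%%): post count exceeds pre", name, r)
        out[name] = r
    return out


def allelic_support_partition(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    atypical_read_names: set[str],
) -> AllelicSupport:
    """Partition read support at a SNV by (typical/atypical) x (ref/alt).

    ``pos`` is 1-based (VCF convention); ``ref`` and ``alt`` must be single
    bases. Each primary record overlapping the position contributes the base
    its CIGAR projects onto the locus; reads that do not overlap after
    projection (deletion or clip at the locus) are excluded and counted.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("allelic support partition is defined for SNVs only")
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            return allelic_support_partition(list(fh), chrom, pos, ref, alt, atypical_read_names)

    rt = at = ra = aa = other = skipped = 0
    target = pos - 1  # 0-based
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        if rec.reference_name != chrom:
            continue
        if not (rec.reference_start <= target < (rec.reference_end or 0)):
            continue
        qpos = None
        for q, r in rec.get_aligned_pairs(matches_only=True):
            if r == target:
                qpos = q
                break
        if qpos is None or rec.query_sequence is None:
            skipped += 1
            continue
        base = rec.query_sequence[qpos].upper()
        is_atypical = rec.query_name in atypical_read_names
        if base == ref.upper():
            ra, rt = (ra + 1, rt) if is_atypical else (ra, rt + 1)
        elif base == alt.upper():
            aa, at = (aa + 1, at) if is_atypical else (aa, at + 1)
        else:
            other += 1
    return AllelicSupport(
        chrom=chrom,
        pos=pos,
        ref_support_typical=rt,
        alt_support_typical=at,
        ref_support_atypical=ra,
        alt_support_atypical=aa,
        other_support=other,
        n_not_overlapping=skipped,
    )


def fraction_variants_attributable(
    vcf_pre: str | Path | Sequence[VariantRecord],
    vcf_post: str | Path | Sequence[VariantRecord],
    clusters: Sequence[AtypicalCluster],
    window: int = 100,
    coding_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> dict[str, float | None]:
    """Percent of pre-decoy variants attributable to atypical alignments.

    A variant is attributable when it is called pre-decoy, disappears
    post-decoy (``lost``), and lies within ``window`` bp of an atypical
    cluster. Returns the percentage over all pre-decoy variants, plus the
    same restricted to coding intervals when a BED-style mapping
    (chrom -> [(start0, end0), ...], half-open) is given. Undefined (None)
    on an empty pre callset.
    """
    pre = read_vcf_records(vcf_pre) if isinstance(vcf_pre, (str, Path)) else list(vcf_pre)
    post = read_vcf_records(vcf_post) if isinstance(vcf_post, (str, Path)) else list(vcf_post)
    if not pre:
        return {"pct_attributable": None, "pct_attributable_coding": None}
    changes, _ = compare_vcfs(pre, post)
    lost = [
        VariantRecord(c.chrom, c.pos, c.ref, c.alt, "./.", c.qual_pre or float("nan"))
        for c in changes
        if c.change_class == "lost"
    ]
    lost_near = variants_near_atypical(lost, clusters, window=window) if lost and clusters else []
    result: dict[str, float | None] = {
        "pct_attributable": 100.0 * len(lost_near) / len(pre)
    }
    if coding_intervals is not None:

        def in_coding(v: VariantRecord) -> bool:
            return any(s < v.pos <= e for s, e in coding_intervals.get(v.chrom, ()))

        pre_coding = [v for v in pre if in_coding(v)]
        lost_coding = [v for v in lost_near if in_coding(v)]
        result["pct_attributable_coding"] = (
            100.0 * len(lost_coding) / len(pre_coding) if pre_coding else None
        )
    else:
        result["pct_attributable_coding"] = None
    return result
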