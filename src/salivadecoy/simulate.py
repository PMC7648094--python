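"""Synthetic fixtures with truth tables for the whole pipeline.

Generates, with full determinism under a fixed seed: a random reference, a
SAM file mixing typical read pairs with planted atypical pairs (both mates
stacked on a short reference core, soft-clipped flanks, |TLEN| = core
length), BLAST tabular + taxonomy tables straddling the census filters, and
pre/post-decoy VCF pairs with a planted genotype-change table. Every emitted
read pair, BLAST query and variant locus has exactly one truth row, so
detection, profiling and genotype-comparison code can be scored exactly.

MAPQ values are assigned from a configured bin mixture, not computed from an
aligner model: the fixtures exercise downstream logic, not aligner
behaviour. Contaminant read flanks are random sequence; pass real genome
FASTA to the planting functions for more realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .impact_report import AlignmentStats

__all__ = [
    "SimConfig",
    "DEFAULT_CONTAMINANT_TAXA",
    "TYPICAL_CONTROL_TAXA",
    "make_reference",
    "write_reference_fasta",
    "plant_atypical_pair",
    "plant_typical_pair",
    "simulate_alignments",
    "make_blast_table",
    "make_vcf_pair",
    "alignment_stats_pre",
    "simulate_decoy_effect",
    "simulate_dataset",
]

# (species, genus, category, weight among assigned queries); bacteria dominate
# as in a saliva contamination census, with minor food-plant, human, fungal
# and viral components
DEFAULT_CONTAMINANT_TAXA: tuple[tuple[str, str, str, float], ...] = (
    ("Streptococcus mitis", "Streptococcus", "Bacteria", 0.33),
    ("Streptococcus salivarius", "Streptococcus", "Bacteria", 0.15),
    ("Haemophilus parainfluenzae", "Haemophilus", "Bacteria", 0.15),
    ("Neisseria subflava", "Neisseria", "Bacteria", 0.12),
    ("Prevotella melaninogenica", "Prevotella", "Bacteria", 0.10),
    ("Rothia mucilaginosa", "Rothia", "Bacteria", 0.075),
    ("Aegilops tauschii", "Aegilops", "Plant", 0.03),
    ("Homo sapiens", "Homo", "Human", 0.02),
    ("Candida albicans", "Candida", "Fungi", 0.015),
    ("Human gammaherpesvirus 4", "Lymphocryptovirus", "Viral", 0.01),
)

# control census for typically aligned reads: overwhelmingly human, a little
# other-primate signal, the rest without a significant database match
TYPICAL_CONTROL_TAXA: tuple[tuple[str, str, str, float], ...] = (
    ("Homo sapiens", "Homo", "Human", 0.9704),
    ("Pan troglodytes", "Pan", "Mammalian other", 0.0296),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a contaminated saliva-derived short-read run: 151 bp
    paired-end reads, typical inserts ~N(400, 50) bp, atypical cores drawn
    uniformly from 19-25 bp, MAPQ bin weights for <=10 / 11-39 / >=40 of
    0.4541 / 0.1219 / 0.4240, and about a third of contaminant BLAST queries
    returning no significant hit.
    """

    seed: int = 1
    ref_name: str = "chr_sim"
    ref_len: int = 100_000
    n_typical_pairs: int = 5000
    n_atypical_pairs: int = 50
    core_len_range: tuple[int, int] = (19, 25)
    read_len: int = 151
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    mapq_mixture: tuple[float, float, float] = (0.4541, 0.1219, 0.4240)
    no_hit_fraction: float = 0.3286
    contaminant_taxa: tuple[tuple[str, str, str, float], ...] = DEFAULT_CONTAMINANT_TAXA
    # VCF planting
    n_restored: int = 20
    n_lost: int = 10
    n_new: int = 5
    n_unchanged: int = 100
    lost_qual_mean: float = 45.0
    lost_qual_sd: float = 10.0
    # alignment census / decoy efficacy conditions
    unaligned_fraction: float = 0.07
    decoy_capture_atypical: float = 0.4366
    decoy_capture_unaligned: float = 0.4484

    def __post_init__(self) -> None:
        lo, hi = self.core_len_range
        if not (1 <= lo <= hi < self.read_len):
            raise ValueError("core_len_range must lie within (1, read_len)")
        w = np.asarray(self.mapq_mixture, float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mapq_mixture weights must be >= 0 and sum to 1")
        tw = sum(t[3] for t in self.contaminant_taxa)
        if self.contaminant_taxa and abs(tw - 1.0) > 1e-6:
            raise ValueError("contaminant taxa weights must sum to 1")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_reference(ref_len: int, seed: int) -> str:
    """Uniform-random A/C/G/T sequence, reproducible by seed."""
    if ref_len < 1000:
        raise ValueError("ref_len must be >= 1000")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=ref_len).tobytes().decode("ascii")


def write_reference_fasta(seq: str, name: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _draw_mapq(rng: np.random.Generator, mixture: tuple[float, float, float]) -> int:
    bin_idx = rng.choice(3, p=mixture)
    lo, hi = ((0, 10), (11, 39), (40, 60))[bin_idx]
    return int(rng.integers(lo, hi + 1))


def _segment(
    header: pysam.AlignmentHeader,
    name: str,
    flag: int,
    pos0: int,
    mapq: int,
    cigar: str,
    pnext0: int,
    tlen: int,
    seq: str,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos0
    a.mapping_quality = mapq
    a.cigarstring = cigar
    a.next_reference_id = 0
    a.next_reference_start = pnext0
    a.template_length = tlen
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def plant_atypical_pair(
    ref: str,
    pos0: int,
    core_len: int,
    read_len: int,
    rng: np.random.Generator,
    header: pysam.AlignmentHeader,
    name: str,
    mapq1: int,
    mapq2: int,
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """Two mates stacked on the reference core at ``pos0`` (0-based).

    Each mate is flank + core + flank with CIGAR ``xS {core}M yS``; both
    start at the core position and |TLEN| equals the core length, the
    geometry of a contaminant pair co-opting a short region of identity.
    Flanks are rejection-sampled so the core k-mer occurs exactly once in
    each read.
    """
    if pos0 < 0 or pos0 + core_len > len(ref):
        raise ValueError("core placement outside reference")
    if core_len > read_len:
        raise ValueError("core longer than read")
    core = ref[pos0 : pos0 + core_len]

    def one_mate() -> tuple[str, int, int]:
        for _ in range(100):
            left = int(rng.integers(5, read_len - core_len - 5 + 1))
            right = read_len - core_len - left
            seq = _random_seq(rng, left) + core + _random_seq(rng, right)
            if seq.count(core) == 1:
                return seq, left, right
        raise RuntimeError("could not place core uniquely in flanks")

    seq1, l1, r1 = one_mate()
    seq2, l2, r2 = one_mate()
    cigar1 = f"{l1}S{core_len}M{r1}S"
    cigar2 = f"{l2}S{core_len}M{r2}S"
    m1 = _segment(header, name, 0x1 | 0x20 | 0x40, pos0, mapq1, cigar1, pos0, core_len, seq1)
    m2 = _segment(header, name, 0x1 | 0x10 | 0x80, pos0, mapq2, cigar2, pos0, -core_len, seq2)
    return m1, m2


def plant_typical_pair(
    ref: str,
    pos0: int,
    read_len: int,
    insert: int,
    header: pysam.AlignmentHeader,
    name: str,
    mapq: int = 60,
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """A proper pair of exact reference substrings with the given insert."""
    if insert <= read_len:
        raise ValueError("insert must exceed read length")
    if pos0 < 0 or pos0 + insert > len(ref):
        raise ValueError("pair placement outside reference")
    p2 = pos0 + insert - read_len
    cigar = f"{read_len}M"
    m1 = _segment(
        header, name, 0x1 | 0x2 | 0x20 | 0x40, pos0, mapq, cigar, p2, insert,
        ref[pos0 : pos0 + read_len],
    )
    m2 = _segment(
        header, name, 0x1 | 0x2 | 0x10 | 0x80, p2, mapq, cigar, pos0, -insert,
        ref[p2 : p2 + read_len],
    )
    return m1, m2


def simulate_alignments(
    config: SimConfig,
    ref: str,
    sam_path: str | Path,
) -> pd.DataFrame:
    """Write a SAM of typical + planted atypical pairs; return the truth table.

    Truth columns: read_name, is_atypical, pos (1-based core/leftmost start),
    core_len, span, mapq1, mapq2. Record order is shuffled so detection
    cannot rely on sorting.
    """
    rng = np.random.default_rng(config.seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": config.ref_name, "LN": len(ref)}],
            "PG": [{"ID": "salivadecoy-sim", "PN": "salivadecoy-sim"}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    truth_rows: list[dict] = []

    min_insert = config.read_len + 5
    for i in range(config.n_typical_pairs):
        insert = max(min_insert, int(round(rng.normal(config.insert_mean, config.insert_sd))))
        pos0 = int(rng.integers(0, len(ref) - insert))
        name = f"typ{i:06d}"
        mapq = 60
        m1, m2 = plant_typical_pair(ref, pos0, config.read_len, insert, header, name, mapq)
        records.extend((m1, m2))
        truth_rows.append(
            dict(read_name=name, is_atypical=False, pos=pos0 + 1, core_len=0,
                 span=insert, mapq1=mapq, mapq2=mapq)
        )

    lo, hi = config.core_len_range
    for i in range(config.n_atypical_pairs):
        core_len = int(rng.integers(lo, hi + 1))
        pos0 = int(rng.integers(0, len(ref) - core_len))
        name = f"atyp{i:06d}"
        mq1 = _draw_mapq(rng, config.mapq_mixture)
        mq2 = _draw_mapq(rng, config.mapq_mixture)
        m1, m2 = plant_atypical_pair(
            ref, pos0, core_len, config.read_len, rng, header, name, mq1, mq2
        )
        records.extend((m1, m2))
        truth_rows.append(
            dict(read_name=name, is_atypical=True, pos=pos0 + 1, core_len=core_len,
                 span=core_len, mapq1=mq1, mapq2=mq2)
        )

    order = rng.permutation(len(records))
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as fh:
        for idx in order:
            fh.write(records[idx])
    return pd.DataFrame(truth_rows)


def make_blast_table(
    query_ids: list[str],
    taxa_weights: tuple[tuple[str, str, str, float], ...],
    no_hit_fraction: float,
    seed: int,
    blast_path: str | Path,
    taxmap_path: str | Path,
    read_len: int = 151,
    sub_threshold_rate: float = 0.3,
) -> pd.DataFrame:
    """Emit a 13-column BLAST table + taxonomy TSV for the given queries.

    Each query either gets no surviving hit (probability ``no_hit_fraction``)
    or a best hit from ``taxa_weights`` with coverage/e-value comfortably
    inside the 80%/1.0 filters, sometimes plus a weaker second hit and, at
    ``sub_threshold_rate``, a distractor row that fails the filters (so
    filtering is actually exercised). Returns the truth table with the
    assigned species/category per query ("No-hit" where none survives).
    """
    rng = np.random.default_rng(seed)
    species = [t[0] for t in taxa_weights]
    weights = np.asarray([t[3] for t in taxa_weights], float)
    weights = weights / weights.sum()
    info = {t[0]: (t[1], t[2]) for t in taxa_weights}
    acc_of = {sp: f"ACC_{i:03d}.1" for i, sp in enumerate(species)}

    rows: list[str] = []
    truth: list[dict] = []

    def hit_row(qid: str, sp: str, bitscore: float, cov: float, evalue: float) -> str:
        alen = int(round(cov * read_len))
        pident = float(rng.uniform(88.0, 100.0))
        qstart = 1
        qend = alen
        sstart = int(rng.integers(1, 10_000))
        return "\t".join(
            [
                qid, acc_of[sp], f"{pident:.3f}", str(alen), str(int(rng.integers(0, 5))),
                str(int(rng.integers(0, 3))), str(qstart), str(qend), str(sstart),
                str(sstart + alen - 1), f"{evalue:.3g}", f"{bitscore:.1f}", str(read_len),
            ]
        )

    for qid in query_ids:
        if rng.random() < no_hit_fraction:
            # optionally a distractor that the filters must reject
            if rng.random() < sub_threshold_rate:
                sp = species[int(rng.choice(len(species), p=weights))]
                if rng.random() < 0.5:
                    rows.append(hit_row(qid, sp, 40.0, float(rng.uniform(0.3, 0.79)), 1e-3))
                else:
                    rows.append(hit_row(qid, sp, 30.0, float(rng.uniform(0.85, 1.0)),
                                        float(rng.uniform(1.01, 10.0))))
            truth.append(dict(query_id=qid, species="No-hit", genus="", category="No-hit"))
            continue
        sp = species[int(rng.choice(len(species), p=weights))]
        best_bits = float(rng.uniform(120.0, 250.0))
        rows.append(
            hit_row(qid, sp, best_bits, float(rng.uniform(0.82, 1.0)),
                    float(10.0 ** rng.uniform(-30, -5)))
        )
        if rng.random() < 0.5:
            other = species[int(rng.choice(len(species), p=weights))]
            rows.append(
                hit_row(qid, other, best_bits - float(rng.uniform(5.0, 50.0)),
                        float(rng.uniform(0.82, 1.0)), float(10.0 ** rng.uniform(-10, -1)))
            )
        genus, category = info[sp]
        truth.append(dict(query_id=qid, species=sp, genus=genus, category=category))

    with open(blast_path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))
    with open(taxmap_path, "w") as fh:
        fh.write("subject_id\tspecies\tgenus\tcategory\n")
        for sp in species:
            genus, category = info[sp]
            fh.write(f"{acc_of[sp]}\t{sp}\t{genus}\t{category}\n")
    return pd.DataFrame(truth)


def make_vcf_pair(
    config: SimConfig,
    ref: str,
    atypical_positions: list[int],
    vcf_pre_path: str | Path,
    vcf_post_path: str | Path,
) -> pd.DataFrame:
    """Write pre/post-decoy VCFs with a planted genotype-change truth table.

    Plants, at distinct loci: ``n_restored`` sites called 0/1 pre and 1/1
    post (the decoy's hallmark correction), ``n_lost`` pre-only sites placed
    within 100 bp of planted atypical cores (QUAL ~ N(lost_qual_mean,
    lost_qual_sd) clipped positive), ``n_new`` post-only sites, and
    ``n_unchanged`` identical sites. Truth columns: chrom, pos, ref, alt,
    change_class, qual_pre, qual_post.
    """
    rng = np.random.default_rng(config.seed + 7)
    used: set[int] = set()

    def fresh_pos(near: int | None = None) -> int:
        for _ in range(1000):
            if near is None:
                p = int(rng.integers(1, len(ref) + 1))
            else:
                p = near + int(rng.integers(-100, 101))
                p = min(max(p, 1), len(ref))
            if p not in used:
                used.add(p)
                return p
        raise RuntimeError("could not place a fresh variant position")

    def snv_at(p: int) -> tuple[str, str]:
        refb = ref[p - 1]
        alts = [b for b in "ACGT" if b != refb]
        return refb, alts[int(rng.integers(0, 3))]

    rows: list[dict] = []
    for _ in range(config.n_unchanged):
        p = fresh_pos()
        r, a = snv_at(p)
        q = float(rng.uniform(50, 1500))
        gt = ("0/1", "1/1")[int(rng.integers(0, 2))]
        rows.append(dict(pos=p, ref=r, alt=a, change_class="unchanged",
                         gt_pre=gt, gt_post=gt, qual_pre=q, qual_post=q))
    for _ in range(config.n_restored):
        p = fresh_pos()
        r, a = snv_at(p)
        rows.append(dict(pos=p, ref=r, alt=a, change_class="restored_hom_alt",
                         gt_pre="0/1", gt_post="1/1",
                         qual_pre=float(rng.uniform(40, 99)),
                         qual_post=float(rng.uniform(100, 1500))))
    anchors = atypical_positions or [None]
    for i in range(config.n_lost):
        near = anchors[i % len(anchors)]
        p = fresh_pos(near)
        r, a = snv_at(p)
        q = float(max(1.0, rng.normal(config.lost_qual_mean, config.lost_qual_sd)))
        rows.append(dict(pos=p, ref=r, alt=a, change_class="lost",
                         gt_pre="0/1", gt_post=None, qual_pre=q, qual_post=None))
    for _ in range(config.n_new):
        p = fresh_pos()
        r, a = snv_at(p)
        rows.append(dict(pos=p, ref=r, alt=a, change_class="new",
                         gt_pre=None, gt_post="0/1",
                         qual_pre=None, qual_post=float(rng.uniform(30, 200))))

    rows.sort(key=lambda d: d["pos"])

    def write_vcf(path: str | Path, which: str) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={config.ref_name},length={len(ref)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n")
            for d in rows:
                gt = d[f"gt_{which}"]
                if gt is None:
                    continue
                qual = d[f"qual_{which}"]
                fh.write(
                    f"{config.ref_name}\t{d['pos']}\t.\t{d['ref']}\t{d['alt']}\t"
                    f"{qual:.2f}\t.\t.\tGT\t{gt}\n"
                )

    write_vcf(vcf_pre_path, "pre")
    write_vcf(vcf_post_path, "post")
    truth = pd.DataFrame(rows)
    truth.insert(0, "chrom", config.ref_name)
    return truth


def alignment_stats_pre(config: SimConfig, truth_pairs: pd.DataFrame) -> AlignmentStats:
    """Pre-decoy alignment census implied by a truth table.

    Atypical pairs are counted at the variant-calling-relevant threshold
    (better mate MAPQ >= 10); unaligned reads are added on top of the aligned
    pool at ``config.unaligned_fraction``.
    """
    atyp = truth_pairs[truth_pairs.is_atypical]
    n_atypical = int((atyp[["mapq1", "mapq2"]].max(axis=1) >= 10).sum())
    n_aligned_reads = 2 * len(truth_pairs)
    n_unaligned = int(round(
        config.unaligned_fraction / (1 - config.unaligned_fraction) * n_aligned_reads
    ))
    return AlignmentStats(
        n_reads_total=n_aligned_reads + n_unaligned,
        n_unaligned=n_unaligned,
        n_atypical_pairs=n_atypical,
        n_mapped_to_decoy=0,
    )


def simulate_decoy_effect(
    stats_pre: AlignmentStats,
    capture_fraction_atypical: float,
    capture_fraction_unaligned: float,
    seed: int,
) -> AlignmentStats:
    """Post-decoy alignment stats: each pre count thinned binomially.

    Each atypical pair (and unaligned read) is independently captured by the
    decoy with the given probability, emulating a decoy that sequesters a
    known fraction of contaminant reads.
    """
    rng = np.random.default_rng(seed)
    captured_atyp = int(rng.binomial(stats_pre.n_atypical_pairs, capture_fraction_atypical))
    captured_unal = int(rng.binomial(stats_pre.n_unaligned, capture_fraction_unaligned))
    return AlignmentStats(
        n_reads_total=stats_pre.n_reads_total,
        n_unaligned=stats_pre.n_unaligned - captured_unal,
        n_atypical_pairs=stats_pre.n_atypical_pairs - captured_atyp,
        n_mapped_to_decoy=2 * captured_atyp + captured_unal,
    )


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture set to ``outdir``; returns a name->path map.

    Produces: ref.fa, aln.sam, truth_pairs.tsv, blast_atypical.tsv,
    taxonomy.tsv, truth_blast.tsv, pre.vcf, post.vcf, truth_changes.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("ref", "ref.fa"), ("sam", "aln.sam"), ("truth_pairs", "truth_pairs.tsv"),
        ("blast", "blast_atypical.tsv"), ("taxmap", "taxonomy.tsv"),
        ("truth_blast", "truth_blast.tsv"), ("vcf_pre", "pre.vcf"),
        ("vcf_post", "post.vcf"), ("truth_changes", "truth_changes.tsv"),
    ]}
    ref = make_reference(config.ref_len, config.seed)
    write_reference_fasta(ref, config.ref_name, paths["ref"])
    truth_pairs = simulate_alignments(config, ref, paths["sam"])
    truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)

    atypical = truth_pairs[truth_pairs.is_atypical]
    truth_blast = make_blast_table(
        list(atypical.read_name),
        config.contaminant_taxa,
        config.no_hit_fraction,
        config.seed + 3,
        paths["blast"],
        paths["taxmap"],
        read_len=config.read_len,
    )
    truth_blast.to_csv(paths["truth_blast"], sep="\t", index=False)

    truth_changes = make_vcf_pair(
        config, ref, list(atypical.pos), paths["vcf_pre"], paths["vcf_post"]
    )
    truth_changes.to_csv(paths["truth_changes"], sep="\t", index=False)
    return paths
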