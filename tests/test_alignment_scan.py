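"""Atypical-pair detection, core geometry, clustering and TLEN filtering."""

import random

import pysam
import pytest

from salivadecoy.alignment_scan import (
    AtypicalCluster,
    AtypicalPair,
    PairAlignment,
    SpanUndefinedError,
    cluster_atypical,
    core_identity_region,
    detect_atypical_pairs,
    filter_by_tlen,
    iter_pair_alignments,
    mapq_profile,
    pair_from_segments,
    scan_sam,
    template_span,
)


def make_pair(m1s, m1e, m2s, m2e, cigar1="151M", cigar2="151M", mapq1=60, mapq2=60,
              tlen=0, name="r", ref="chr1"):
    return PairAlignment(
        read_name=name, ref_name=ref, mate1_start=m1s, mate1_end=m1e,
        mate2_start=m2s, mate2_end=m2e, cigar1=cigar1, cigar2=cigar2,
        mapq1=mapq1, mapq2=mapq2, tlen=tlen,
    )


@pytest.mark.parametrize(
    "coords,expected",
    [
        ((1000, 1021, 1000, 1021), 22),   # stacked mates on one 22 bp core
        ((500, 650, 800, 950), 451),      # normal insert
        ((100, 130, 105, 120), 31),       # nested mate
    ],
)
def test_template_span_is_inclusive_extent(coords, expected):
    assert template_span(make_pair(*coords)) == expected


def test_span_undefined_for_unmapped_or_cross_reference():
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chr1", "LN": 10000}, {"SN": "chr2", "LN": 10000}]}
    )

    def seg(flag, rid=0, pos=100, cigar="10M"):
        a = pysam.AlignedSegment(header)
        a.query_name = "q"
        a.flag = flag
        a.reference_id = rid
        a.reference_start = pos
        a.cigarstring = cigar
        a.query_sequence = "A" * 10
        return a

    mapped = seg(0x1 | 0x40)
    unmapped = seg(0x1 | 0x4 | 0x80, cigar=None)
    unmapped.cigarstring = None
    with pytest.raises(SpanUndefinedError):
        pair_from_segments(mapped, unmapped)
    with pytest.raises(SpanUndefinedError):
        pair_from_segments(seg(0x1 | 0x40, rid=0), seg(0x1 | 0x80, rid=1))


def test_detection_boundary_at_30bp():
    inside = make_pair(1000, 1029, 1000, 1029, "30M", "30M")
    outside = make_pair(1000, 1030, 1000, 1030, "31M", "31M")
    got = detect_atypical_pairs([inside, outside])
    assert [p.pair.mate1_end for p in got] == [1029]
    assert got[0].span_bp == 30


def test_min_mapq_uses_better_mate():
    pair = make_pair(1000, 1021, 1000, 1021, "60S22M69S", "45S22M84S", mapq1=5, mapq2=45)
    assert detect_atypical_pairs([pair], min_mapq=10)
    assert not detect_atypical_pairs([pair], min_mapq=50)


def test_core_identity_region_soft_clipped_pair():
    pair = make_pair(1000, 1021, 1000, 1021, "60S22M69S", "45S22M84S")
    core_start, core_end, clip_l, clip_r = core_identity_region(pair)
    assert (core_start, core_end) == (1000, 1021)
    assert core_end - core_start + 1 == 22
    assert clip_l == (60, 45)
    assert clip_r == (69, 84)


def test_core_identity_region_full_match_read():
    pair = make_pair(1000, 1150, 1000, 1150, "151M", "151M")
    core_start, core_end, clip_l, clip_r = core_identity_region(pair)
    assert core_end - core_start + 1 == 151
    assert clip_l == (0, 0) and clip_r == (0, 0)


def test_core_identity_no_ref_consuming_op_is_error():
    pair = make_pair(1000, 1000, 1000, 1000, "151S", "151M")
    with pytest.raises(ValueError, match="reference-consuming"):
        core_identity_region(pair)


def test_malformed_cigar_is_skipped_and_counted():
    from salivadecoy.alignment_scan import ScanCounts

    bad = make_pair(1000, 1021, 1000, 1021, "60Sfoo", "45S22M84S")
    counts = ScanCounts()
    assert detect_atypical_pairs([bad], counts=counts) == []
    assert counts.n_malformed_cigar == 1


def test_detection_matches_truth_on_simulated_file(sim_dataset, truth_pairs):
    pairs, counts = scan_sam(sim_dataset["sam"])
    detected = {p.pair.read_name for p in pairs}
    planted = set(truth_pairs[truth_pairs.is_atypical].read_name)
    assert detected == planted
    assert counts.n_singletons == 0
    # spans and cores match the truth table exactly
    truth = truth_pairs.set_index("read_name")
    for p in pairs:
        row = truth.loc[p.pair.read_name]
        assert p.span_bp == row.span == p.core_len_bp == row.core_len
        assert p.core_start == row.pos


def test_detection_is_order_invariant(sim_dataset, tmp_path):
    records = []
    with pysam.AlignmentFile(str(sim_dataset["sam"]), check_sq=False) as fh:
        header = fh.header
        records = list(fh)
    random.Random(5).shuffle(records)
    shuffled = tmp_path / "shuffled.sam"
    with pysam.AlignmentFile(str(shuffled), "w", header=header) as out:
        for r in records:
            out.write(r)
    a = {p.pair.read_name for p in scan_sam(sim_dataset["sam"])[0]}
    b = {p.pair.read_name for p in scan_sam(shuffled)[0]}
    assert a == b


def make_atypical(core_start, core_end, ref="chr1", name=None, mapq1=60, mapq2=60):
    length = core_end - core_start + 1
    pair = make_pair(
        core_start, core_end, core_start, core_end,
        f"10S{length}M10S", f"10S{length}M10S",
        mapq1=mapq1, mapq2=mapq2,
        name=name or f"r{core_start}", ref=ref,
    )
    return AtypicalPair(
        pair=pair, span_bp=length, core_start=core_start, core_end=core_end,
        core_len_bp=length, clip_left_bp=(10, 10), clip_right_bp=(10, 10),
    )


def test_cluster_merges_within_gap():
    pairs = [make_atypical(100, 121), make_atypical(130, 151)]
    clusters = cluster_atypical(pairs, merge_gap=20)
    assert len(clusters) == 1
    assert (clusters[0].start, clusters[0].end, clusters[0].n_pairs) == (100, 151, 2)


def test_cluster_splits_beyond_gap():
    pairs = [make_atypical(100, 121), make_atypical(200, 221)]
    assert len(cluster_atypical(pairs, merge_gap=20)) == 2


def _oracle_cluster(pairs, merge_gap):
    """O(n^2) repeated all-pairs merging."""
    groups = [
        {"ref": p.pair.ref_name, "start": p.core_start, "end": p.core_end, "n": 1}
        for p in pairs
    ]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if a["ref"] != b["ref"]:
                    continue
                gap = max(a["start"], b["start"]) - min(a["end"], b["end"]) - 1
                if gap <= merge_gap:
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["n"] += b["n"]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return sorted((g["ref"], g["start"], g["end"], g["n"]) for g in groups)


@pytest.mark.parametrize("seed", range(5))
def test_cluster_matches_quadratic_oracle(seed):
    rng = random.Random(seed)
    pairs = []
    for i in range(300):
        start = rng.randint(1, 20_000)
        end = start + rng.randint(18, 24)
        pairs.append(make_atypical(start, end, ref=rng.choice(["chr1", "chr2"]), name=f"r{i}"))
    merge_gap = rng.choice([0, 5, 20, 100])
    got = sorted(
        (c.ref_name, c.start, c.end, c.n_pairs) for c in cluster_atypical(pairs, merge_gap)
    )
    assert got == _oracle_cluster(pairs, merge_gap)
    # partition: every pair lands in exactly one cluster
    names = sorted(
        n for c in cluster_atypical(pairs, merge_gap) for n in c.member_read_names
    )
    assert names == sorted(p.pair.read_name for p in pairs)


def test_mapq_profile_fractions():
    pairs = [make_atypical(100, 121, mapq1=0, mapq2=5), make_atypical(200, 221, mapq1=60, mapq2=60)]
    prof = mapq_profile(pairs)
    assert prof.frac_le_10 == 0.5
    assert prof.frac_ge_40 == 0.5
    assert prof.frac_le_10 + prof.frac_mid + prof.frac_ge_40 == pytest.approx(1.0)
    assert sum(prof.histogram.values()) == 4


def test_mapq_profile_degenerate_and_empty():
    allhigh = mapq_profile([make_atypical(100, 121, mapq1=60, mapq2=60)])
    assert allhigh.frac_le_10 == 0.0 and allhigh.frac_ge_40 == 1.0
    empty = mapq_profile([])
    assert empty.frac_le_10 is None and empty.frac_ge_40 is None


def test_mapq_profile_per_pair_convention():
    pairs = [make_atypical(100, 121, mapq1=5, mapq2=45)]
    assert mapq_profile(pairs, unit="pair").frac_ge_40 == 1.0
    assert mapq_profile(pairs, unit="alignment").frac_ge_40 == 0.5


def test_mapq_mixture_recovered_within_sampling_error(truth_pairs, sim_config):
    import numpy as np

    atyp = truth_pairs[truth_pairs.is_atypical]
    mapqs = np.concatenate([atyp.mapq1.to_numpy(), atyp.mapq2.to_numpy()])
    n = len(mapqs)
    frac = (mapqs <= 10).mean()
    p = sim_config.mapq_mixture[0]
    assert abs(frac - p) <= 3 * (p * (1 - p) / n) ** 0.5


def test_filter_remove_drops_planted_pairs_only(sim_dataset, truth_pairs, tmp_path):
    out = tmp_path / "removed.sam"
    report = filter_by_tlen(sim_dataset["sam"], out, mode="remove")
    n_atypical = int(truth_pairs.is_atypical.sum())
    assert report.n_records_removed == 2 * n_atypical
    assert report.n_records_out == report.n_records_in - 2 * n_atypical
    # conservation: output names + removed names = input names
    with pysam.AlignmentFile(str(out), check_sq=False) as fh:
        kept = [r.query_name for r in fh]
    planted = set(truth_pairs[truth_pairs.is_atypical].read_name)
    assert not (set(kept) & planted)
    assert len(kept) == 2 * int((~truth_pairs.is_atypical).sum())


def test_filter_annotate_tags_without_dropping(sim_dataset, truth_pairs, tmp_path):
    out = tmp_path / "annotated.sam"
    report = filter_by_tlen(sim_dataset["sam"], out, mode="annotate")
    assert report.n_records_out == report.n_records_in
    n_atypical = int(truth_pairs.is_atypical.sum())
    assert report.n_records_annotated == 2 * n_atypical
    with pysam.AlignmentFile(str(out), check_sq=False) as fh:
        tagged = [r.query_name for r in fh if r.has_tag("ZA")]
    assert set(tagged) == set(truth_pairs[truth_pairs.is_atypical].read_name)


def test_filter_identity_when_no_atypical_pairs(tmp_path):
    import numpy as np

    from salivadecoy.simulate import SimConfig, make_reference, simulate_alignments

    cfg = SimConfig(seed=21, ref_len=20_000, n_typical_pairs=50, n_atypical_pairs=0)
    ref = make_reference(cfg.ref_len, cfg.seed)
    sam_in = tmp_path / "clean.sam"
    simulate_alignments(cfg, ref, sam_in)
    sam_out = tmp_path / "out.sam"
    report = filter_by_tlen(sam_in, sam_out, mode="remove")
    assert report.n_records_removed == 0
    with pysam.AlignmentFile(str(sam_in), check_sq=False) as a, \
            pysam.AlignmentFile(str(sam_out), check_sq=False) as b:
        ra, rb = list(a), list(b)
    assert [r.to_string() for r in ra] == [r.to_string() for r in rb]


def test_orphan_record_is_annotated_not_removed(tmp_path):
    header = pysam.AlignmentHeader.from_dict({"SQ": [{"SN": "chr1", "LN": 10000}]})
    a = pysam.AlignedSegment(header)
    a.query_name = "orphan"
    a.flag = 0x1 | 0x40
    a.reference_id = 0
    a.reference_start = 999
    a.mapping_quality = 30
    a.cigarstring = "20S22M109S"
    a.next_reference_id = 0
    a.next_reference_start = 999
    a.template_length = 22
    a.query_sequence = "A" * 151
    sam_in = tmp_path / "orphan.sam"
    with pysam.AlignmentFile(str(sam_in), "w", header=header) as fh:
        fh.write(a)
    out = tmp_path / "out.sam"
    report = filter_by_tlen(sam_in, out, mode="remove")
    assert report.n_records_removed == 0
    assert report.n_orphans_annotated == 1
    with pysam.AlignmentFile(str(out), check_sq=False) as fh:
        recs = list(fh)
    assert len(recs) == 1 and recs[0].get_tag("ZA") == 22


def test_iter_pairs_counts_cross_reference(tmp_path):
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chr1", "LN": 10000}, {"SN": "chr2", "LN": 10000}]}
    )

    def seg(name, flag, rid, pos):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = flag
        a.reference_id = rid
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = "20M"
        a.next_reference_id = 1 - rid
        a.next_reference_start = pos
        a.query_sequence = "A" * 20
        return a

    sam = tmp_path / "cross.sam"
    with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
        fh.write(seg("x", 0x1 | 0x40, 0, 100))
        fh.write(seg("x", 0x1 | 0x80, 1, 100))
    from salivadecoy.alignment_scan import ScanCounts

    counts = ScanCounts()
    assert list(iter_pair_alignments(sam, counts)) == []
    assert counts.n_unmapped_or_cross_ref == 1
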