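"""Construction and masking of the bacterial decoy contig.

The decoy is a single artificial contig made by concatenating selected
bacterial genome sequences, separated by runs of 1000 N so that no read can
align across a junction. Three classes of region are then masked to N so the
decoy only ever *gains* reads that belong to it:

* regions highly similar to the human genome (>= 65% identity by default),
  which would otherwise steal genuinely human reads;
* short-unit tandem ("polynucleotide") repeats, which attract low-complexity
  reads from anywhere;
* regions represented more than once within the decoy, which would split
  mapping quality between copies (all copies after the first are masked).

Decoy coordinates are 0-based half-open throughout; FASTA output is wrapped
at 60 columns.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "DecoySequence",
    "MaskInterval",
    "concatenate_decoy",
    "find_human_similar_regions",
    "find_polynucleotide_repeats",
    "find_internal_duplicates",
    "mask_intervals",
    "merge_intervals",
    "append_decoy_to_reference",
    "read_fasta_records",
    "write_fasta",
]

_VALID = set("ACGTN")
MASK_REASONS = ("human_similar", "polynucleotide_repeat", "internal_duplicate")


@dataclass(frozen=True)
class MaskInterval:
    """0-based half-open decoy interval scheduled for N-masking."""

    start: int
    end: int
    reason: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty/inverted mask interval [{self.start}, {self.end})")
        if self.reason not in MASK_REASONS:
            raise ValueError(f"unknown mask reason {self.reason!r}")


@dataclass(frozen=True)
class DecoySequence:
    """The concatenated decoy with its component index.

    ``components`` is an ordered list of ``(source_name, start_offset,
    length)`` so that any decoy coordinate outside a spacer maps back to its
    source genome.
    """

    sequence: str
    components: tuple[tuple[str, int, int], ...]
    spacer_len: int

    def __len__(self) -> int:
        return len(self.sequence)

    def source_coordinate(self, pos: int) -> tuple[str, int] | None:
        """Map a decoy coordinate to (source_name, offset), or None in a spacer."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(pos)
        for name, off, length in self.components:
            if off <= pos < off + length:
                return name, pos - off
        return None


def _normalise(seq: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(b if b in _VALID else "N" for b in seq)


def concatenate_decoy(
    records: Sequence[tuple[str, str]],
    spacer_len: int = 1000,
) -> DecoySequence:
    """Concatenate named sequences into one decoy, spacer_len N between them.

    Sequences are uppercased and IUPAC ambiguity codes become N; soft-masked
    (lowercase) input is treated as ordinary sequence. An empty component is a
    hard error naming the offender.
    """
    if not records:
        raise ValueError("no sequences to concatenate")
    parts: list[str] = []
    components: list[tuple[str, int, int]] = []
    offset = 0
    for i, (name, seq) in enumerate(records):
        if not seq:
            raise ValueError(f"component {name!r} is empty")
        if i > 0:
            parts.append("N" * spacer_len)
            offset += spacer_len
        clean = _normalise(seq)
        parts.append(clean)
        components.append((name, offset, len(clean)))
        offset += len(clean)
    return DecoySequence(
        sequence="".join(parts), components=tuple(components), spacer_len=spacer_len
    )


def merge_intervals(intervals: Iterable[MaskInterval]) -> list[MaskInterval]:
    """Merge overlapping/adjacent intervals per reason; sorted output."""
    by_reason: dict[str, list[MaskInterval]] = defaultdict(list)
    for iv in intervals:
        by_reason[iv.reason].append(iv)
    out: list[MaskInterval] = []
    for reason, ivs in by_reason.items():
        ivs.sort(key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(MaskInterval(cur_s, cur_e, reason))
                cur_s, cur_e = iv.start, iv.end
        out.append(MaskInterval(cur_s, cur_e, reason))
    out.sort(key=lambda x: (x.start, x.end, x.reason))
    return out


def _identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of the whole query into target.

    Defined as ``1 - edit_distance / len(query)`` with the edit distance of
    the optimal alignment of the full query inside the target (free target
    overhangs). Normalising by the window length rather than by alignment
    columns keeps gap-heavy reroutes from inflating identity.
    """
    if not query:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    ed = res["editDistance"]
    if ed < 0:
        return 0.0
    return max(0.0, 1.0 - ed / len(query))


def find_human_similar_regions(
    decoy: DecoySequence,
    human_seq: str,
    min_identity: float = 0.65,
    window: int = 100,
    step: int = 50,
    seed_k: int = 12,
) -> list[MaskInterval]:
    """Screen decoy windows for human-like sequence via seed-and-extend.

    The decoy is tiled with ``window``-bp windows every ``step`` bp. A window
    is a candidate when it shares at least one exact ``seed_k``-mer with the
    human sequence; candidates are aligned (infix, edit-distance optimal)
    against the seeded human neighbourhood and masked when
    ``1 - edit_distance/window`` reaches ``min_identity``. Overlapping masked
    windows are merged.

    The human sequence may be a whole small reference or one chromosome;
    callers with multi-contig references run once per contig and merge.
    """
    human = _normalise(human_seq)
    dec = decoy.sequence
    if not human or not dec:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(human) - seed_k + 1):
        kmer = human[i : i + seed_k]
        if "N" not in kmer:
            index[kmer].append(i)

    if window > len(dec):
        window = len(dec)  # degenerate: single whole-sequence test
    slack = max(10, window // 5)
    hits: list[MaskInterval] = []
    starts = list(range(0, len(dec) - window + 1, step))
    if starts and starts[-1] != len(dec) - window:
        starts.append(len(dec) - window)
    for ws in starts:
        w = dec[ws : ws + window]
        if w.count("N") > window // 2:
            continue
        # seed positions in human, de-duplicated by neighbourhood
        cand: set[int] = set()
        for off in range(0, window - seed_k + 1):
            kmer = w[off : off + seed_k]
            if "N" in kmer:
                continue
            for hp in index.get(kmer, ()):
                cand.add(max(0, hp - off - slack))
        if not cand:
            continue
        masked = False
        for tstart in sorted(cand):
            target = human[tstart : tstart + window + 2 * slack]
            if len(target) < window // 2:
                continue
            if _identity(w, target) >= min_identity:
                masked = True
                break
        if masked:
            hits.append(MaskInterval(ws, ws + window, "human_similar"))
    return merge_intervals(hits)


def find_polynucleotide_repeats(
    decoy: DecoySequence | str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_total_len: int = 20,
) -> list[MaskInterval]:
    """Find maximal short-unit tandem repeats (unit length min_unit..max_unit).

    A run qualifies when ``seq[i] == seq[i-u]`` holds across a stretch of at
    least ``min_total_len`` bp containing at least two full units. Runs of N
    (the spacers) are ignored. Nested and overlapping runs are merged.
    """
    seq = decoy.sequence if isinstance(decoy, DecoySequence) else decoy
    n = len(seq)
    found: list[MaskInterval] = []
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u < n:
            if seq[i + u] != seq[i] or seq[i] == "N":
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            run_len = j - i
            if run_len >= max(min_total_len, 2 * u):
                found.append(MaskInterval(i, j, "polynucleotide_repeat"))
            i = j - u + 1
    return merge_intervals(found)


def find_internal_duplicates(
    decoy: DecoySequence | str,
    min_len: int = 100,
    k: int = 21,
    max_kmer_occ: int = 64,
) -> list[MaskInterval]:
    """Find regions exactly repeated within the decoy; mask all but the first.

    Shared k-mers between distinct decoy positions are chained along
    diagonals; a chain of consecutive shared k-mers is an exact repeat, and
    every copy after the leftmost is reported for masking. k-mers occurring
    more than ``max_kmer_occ`` times are skipped (hyper-repetitive sequence is
    the tandem-repeat masker's job).
    """
    seq = decoy.sequence if isinstance(decoy, DecoySequence) else decoy
    n = len(seq)
    occ: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            occ[kmer].append(i)

    # matched (p, q) k-mer start pairs grouped by diagonal q - p, p < q
    diagonals: dict[int, list[int]] = defaultdict(list)
    for positions in occ.values():
        if len(positions) < 2 or len(positions) > max_kmer_occ:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                diagonals[positions[b] - positions[a]].append(positions[a])

    out: list[MaskInterval] = []
    for diag, ps in diagonals.items():
        ps = sorted(set(ps))
        run_start = ps[0]
        prev = ps[0]
        for p in ps[1:] + [None]:  # type: ignore[list-item]
            if p is not None and p == prev + 1:
                prev = p
                continue
            rep_len = prev - run_start + k
            if rep_len >= min_len:
                q0 = run_start + diag
                out.append(MaskInterval(q0, q0 + rep_len, "internal_duplicate"))
            if p is not None:
                run_start = prev = p
    return merge_intervals(out)


def mask_intervals(
    decoy: DecoySequence,
    intervals: Iterable[MaskInterval],
) -> DecoySequence:
    """Replace every base inside the intervals with N; length preserved.

    Idempotent, and commutative across the three mask passes since each pass
    only ever writes N.
    """
    seq = bytearray(decoy.sequence, "ascii")
    n = len(seq)
    for iv in intervals:
        if iv.start < 0 or iv.end > n:
            raise ValueError(f"mask interval [{iv.start}, {iv.end}) outside decoy of length {n}")
        seq[iv.start : iv.end] = b"N" * (iv.end - iv.start)
    return DecoySequence(
        sequence=seq.decode("ascii"), components=decoy.components, spacer_len=decoy.spacer_len
    )


def read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA into ordered (name, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def append_decoy_to_reference(
    reference_fasta: str | Path,
    decoy: DecoySequence,
    contig_name: str,
    out_fasta: str | Path,
) -> None:
    """Write reference contigs in order plus the decoy as a final contig.

    The decoy contig name must not collide with an existing reference contig;
    output is 60-column wrapped and indexable by standard FASTA indexers.
    """
    records = read_fasta_records(reference_fasta)
    if any(name == contig_name for name, _ in records):
        raise ValueError(f"contig name {contig_name!r} already present in reference")
    write_fasta(records + [(contig_name, decoy.sequence)], out_fasta)


def masks_to_bed(intervals: Sequence[MaskInterval], path: str | Path, chrom: str) -> None:
    """Write mask intervals as BED with a reason column."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{iv.reason}\n")


def components_to_tsv(decoy: DecoySequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_name\tstart_offset\tlength\n")
        for name, off, length in decoy.components:
            fh.write(f"{name}\t{off}\t{length}\n")
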