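"""Taxonomic profiling of BLAST hits and decoy genus/species selection.

Reads that align atypically to the human reference (or fail to align at all)
are queried against a nucleotide database with BLAST; this module consumes
the tabular (outfmt-6 style) output, applies the coverage/e-value filters,
assigns each query read to the taxon of its best surviving hit, tallies
counts per species, genus and high-level category, and selects the genera and
species that go into the bacterial decoy.

Taxonomy is supplied as a TSV lookup (subject accession -> species, genus,
category) rather than queried live, so runs are reproducible offline. The
eleven category labels follow the standard breakdown of a RefSeq census:
Archaea, Bacteria, Fungi, Invertebrate, Plant, Protozoa, Human,
Mammalian other, Vertebrate other, Viral, plus No-hit for queries with no
surviving hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "BlastHit",
    "TaxonInfo",
    "TaxonTally",
    "parse_blast_tab",
    "read_taxon_map",
    "filter_hits",
    "assign_queries",
    "tally_taxa",
    "select_decoy_genera",
    "select_additional_species",
]

CATEGORIES = (
    "Archaea",
    "Bacteria",
    "Fungi",
    "Invertebrate",
    "Plant",
    "Protozoa",
    "Human",
    "Mammalian other",
    "Vertebrate other",
    "Viral",
    "No-hit",
)

NO_HIT = "No-hit"
UNMAPPED_SUBJECT = "Unmapped-subject"


@dataclass(frozen=True)
class BlastHit:
    """One BLAST tabular row with derived query coverage."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    evalue: float
    bitscore: float
    query_len: int
    query_cov: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_cov <= 1.0 + 1e-9:
            raise ValueError(f"query coverage {self.query_cov} outside [0, 1]")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class TaxonInfo:
    species: str
    genus: str
    category: str


@dataclass
class TaxonTally:
    """Aggregated per-species / per-genus / per-category counts.

    Category fractions are reported under two denominators because a census
    table can be stated either way: ``category_frac_all`` divides by every
    query including No-hit; ``category_frac_assigned`` divides by assigned
    queries only.
    """

    per_species: dict[str, int] = field(default_factory=dict)
    per_genus: dict[str, int] = field(default_factory=dict)
    per_category: dict[str, int] = field(default_factory=dict)
    n_queries_total: int = 0
    n_queries_no_hit: int = 0
    n_queries_unmapped_subject: int = 0

    @property
    def n_assigned(self) -> int:
        return self.n_queries_total - self.n_queries_no_hit - self.n_queries_unmapped_subject

    @property
    def category_frac_all(self) -> dict[str, float]:
        n = self.n_queries_total
        return {c: v / n for c, v in self.per_category.items()} if n else {}

    @property
    def category_frac_assigned(self) -> dict[str, float]:
        n = self.n_assigned
        return {
            c: v / n for c, v in self.per_category.items() if c not in (NO_HIT, UNMAPPED_SUBJECT)
        } if n else {}

    def species_frac_assigned(self, species: str) -> float:
        return self.per_species.get(species, 0) / self.n_assigned if self.n_assigned else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Category breakdown as a tidy table (count + both fractions)."""
        rows = []
        for cat in list(CATEGORIES) + [UNMAPPED_SUBJECT]:
            n = self.per_category.get(cat, 0)
            if n == 0 and cat == UNMAPPED_SUBJECT:
                continue
            rows.append(
                {
                    "category": cat,
                    "count": n,
                    "frac_all_queries": self.category_frac_all.get(cat, 0.0),
                    "frac_assigned": self.category_frac_assigned.get(cat, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def parse_blast_tab(
    path: str | Path,
    read_lengths: Mapping[str, int] | None = None,
) -> list[BlastHit]:
    """Parse BLAST tabular output (12 standard columns, optional 13th qlen).

    Query coverage is ``align_len / query_len``; the query length comes from
    the optional 13th column, else from ``read_lengths``. Malformed rows are
    warned about and skipped (count in the log); a missing query-length source
    is a hard error because coverage filtering is meaningless without it.
    """
    hits: list[BlastHit] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                n_bad += 1
                logger.warning("%s:%d: %d columns (<12), skipped", path, lineno, len(fields))
                continue
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                alen = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                if len(fields) >= 13:
                    qlen = int(fields[12])
                elif read_lengths is not None:
                    qlen = read_lengths[qid]
                else:
                    raise KeyError("no qlen column and no read-length table supplied")
                hits.append(
                    BlastHit(
                        query_id=qid,
                        subject_id=sid,
                        pct_identity=pident,
                        align_len=alen,
                        evalue=evalue,
                        bitscore=bitscore,
                        query_len=qlen,
                        query_cov=min(alen / qlen, 1.0),
                    )
                )
            except KeyError as exc:
                raise ValueError(
                    f"{path}:{lineno}: cannot determine query length ({exc}); "
                    "supply a 13th qlen column or a read-length table"
                ) from exc
            except ValueError as exc:
                n_bad += 1
                logger.warning("%s:%d: malformed row (%s), skipped", path, lineno, exc)
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)
    return hits


def read_taxon_map(path: str | Path) -> dict[str, TaxonInfo]:
    """Read the accession -> (species, genus, category) lookup TSV.

    Columns: subject_id, species, genus, category (header optional). Every
    category must be one of the recognised labels.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(df.iloc[0]) == ["subject_id", "species", "genus", "category"]:
        df = df.iloc[1:]
    out: dict[str, TaxonInfo] = {}
    valid = set(CATEGORIES) - {NO_HIT}
    for _, row in df.iterrows():
        sid, species, genus, category = row.iloc[0], row.iloc[1], row.iloc[2], row.iloc[3]
        if category not in valid:
            raise ValueError(f"unknown taxon category {category!r} for {sid}")
        out[sid] = TaxonInfo(species=species, genus=genus, category=category)
    return out


def filter_hits(
    hits: Iterable[BlastHit],
    min_query_cov: float = 0.80,
    max_evalue: float = 1.0,
) -> list[BlastHit]:
    """Keep hits covering >= ``min_query_cov`` of the read at e-value <= ``max_evalue``.

    The defaults (80% query coverage, e-value 1.0) define a "positive" BLAST
    result for the contamination census.
    """
    return [h for h in hits if h.query_cov >= min_query_cov and h.evalue <= max_evalue]


def assign_queries(
    hits: Iterable[BlastHit],
    taxon_map: Mapping[str, TaxonInfo],
    query_ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Assign each query the species of its best hit.

    Best = highest bitscore; ties broken by lowest e-value, then lexicographic
    subject id, so assignment is deterministic and order-invariant. Queries
    listed in ``query_ids`` with no surviving hit map to ``No-hit``; hits whose
    subject is absent from the taxonomy are reported as ``Unmapped-subject``.
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    out: dict[str, str] = {}
    for qid, h in best.items():
        info = taxon_map.get(h.subject_id)
        out[qid] = info.species if info is not None else UNMAPPED_SUBJECT
    if query_ids is not None:
        for qid in query_ids:
            out.setdefault(qid, NO_HIT)
    return out


def _hit_rank(h: BlastHit) -> tuple[float, float, str]:
    return (-h.bitscore, h.evalue, h.subject_id)


def tally_taxa(
    assignments: Mapping[str, str],
    taxon_map: Mapping[str, TaxonInfo],
) -> TaxonTally:
    """Roll per-query species assignments up to species/genus/category tallies."""
    species_by_name = {info.species: info for info in taxon_map.values()}
    tally = TaxonTally()
    for _qid, species in assignments.items():
        tally.n_queries_total += 1
        if species == NO_HIT:
            tally.n_queries_no_hit += 1
            tally.per_category[NO_HIT] = tally.per_category.get(NO_HIT, 0) + 1
            continue
        if species == UNMAPPED_SUBJECT:
            tally.n_queries_unmapped_subject += 1
            tally.per_category[UNMAPPED_SUBJECT] = tally.per_category.get(UNMAPPED_SUBJECT, 0) + 1
            continue
        info = species_by_name[species]
        tally.per_species[species] = tally.per_species.get(species, 0) + 1
        tally.per_genus[info.genus] = tally.per_genus.get(info.genus, 0) + 1
        tally.per_category[info.category] = tally.per_category.get(info.category, 0) + 1
    return tally


def select_decoy_genera(
    tally: TaxonTally,
    n_total_reads: int,
    min_freq: float = 1e-5,
) -> list[str]:
    """Genera whose assigned-read frequency reaches ``min_freq`` of all reads.

    Built from a BLAST census of *unaligned* reads (a richer sample of the
    microbial diversity than the sparse atypical set); ``n_total_reads`` is
    the size of that unaligned-read pool. The default 1e-5 is the 0.001%
    inclusion threshold. Sorted by descending count, ties alphabetical.
    """
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    chosen = [
        (genus, n) for genus, n in tally.per_genus.items() if n / n_total_reads >= min_freq
    ]
    chosen.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in chosen]


def select_additional_species(
    atypical_tally: TaxonTally,
    min_fraction: float = 0.02,
    selected_genera: Sequence[str] = (),
    taxon_map: Mapping[str, TaxonInfo] | None = None,
) -> list[str]:
    """Species to add on top of the genus selection.

    From the BLAST census of *atypically aligned* reads, keep species holding
    at least ``min_fraction`` (default 2%) of positive (assigned) results,
    dropping species whose genus is already selected. This guards against a
    contaminant that drives atypical alignments yet is too rare among
    unaligned reads to pass the genus threshold.
    """
    if atypical_tally.n_assigned == 0:
        return []
    genera = set(selected_genera)
    out = []
    for species, n in sorted(atypical_tally.per_species.items(), key=lambda t: (-t[1], t[0])):
        if n / atypical_tally.n_assigned < min_fraction:
            continue
        if taxon_map is not None:
            info = next((i for i in taxon_map.values() if i.species == species), None)
            if info is not None and info.genus in genera:
                continue
        out.append(species)
    return out
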