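# Methods

## The phenomenon being modelled

Short-read aligners report every alignment that clears their scoring
thresholds. A read of microbial origin that shares a short k-mer
(seed-length scale, 19–25 bp) with the human reference can therefore be
placed on the human genome: the shared region aligns, everything else is
soft-clipped. Because both mates of a fragment carry microbial sequence
drawn from the same template, both tend to anchor on the *same* reference
k-mer, so the pair's mapped extent collapses to the core length. The
signature used throughout this package is therefore a property of mapping
geometry alone: both mates mapped to one reference, leftmost-to-rightmost
extent between 1 and 30 bp.

Downstream, these pairs inflate depth locally and always carry the
reference base across their core, which biases allelic depth at overlapping
SNVs toward the reference and converts true 1/1 genotypes into called 0/1.
The mitigation modelled here is a *decoy*: an extra contig of concatenated
microbial genomes appended to the reference, so contaminant reads align
there (with their full length, hence better scores) instead of onto short
human cores.

## Detection (`alignment_scan`)

**Span definition.** The pair span is recomputed from mapped coordinates as
an inclusive length, `max(end1, end2) − min(start1, start2) + 1`, rather
than read from the TLEN field. TLEN conventions vary by aligner (and TLEN
is undefined for some orphan configurations); coordinate recomputation is
aligner-independent. When a record's |TLEN| disagrees with the recomputed
span, the span wins and the disagreement is counted and logged. The
detection window is 1–30 bp inclusive at both ends.

**Eligibility.** Only primary, non-duplicate, non-supplementary records are
paired (mirroring pipelines that mark duplicates before calling). Pairing
uses a single-pass name index that holds only currently-unpaired mates, so
memory is bounded by the number of unpaired reads in flight; leftover
singletons are counted. Unmapped and cross-reference pairs raise/record a
"span undefined" signal and never enter detection.

**Core geometry.** The core interval is the union of reference-consuming
CIGAR operations (`M/D/N/=/X`) across both mates; leading/trailing `S`
operations give per-mate clip lengths. Both mates' cores are recorded
separately (as the per-mate clip tuples) rather than asserting they
coincide.

**MAPQ conventions.** Census fractions (≤ 10 / 11–39 / ≥ 40) are reported
per alignment record by default, and alternatively per pair (scored at the
better mate), since either convention is defensible for "fraction of
atypical alignments". Detection defaults to `min_mapq = 0` (census);
impact analysis uses `min_mapq = 10`, the threshold below which variant
callers discard alignments anyway.

**Clustering.** Core intervals are merged single-linkage when the gap
between them is ≤ 20 bp (the spacing scale of the anomalous variant
clusters this phenomenon produces); the gap is configurable. Clusters are
exported as 0-based half-open BED; all internal SAM-derived coordinates are
1-based inclusive.

**Filtering.** `remove` mode drops every record sharing the read name of an
atypical pair; `annotate` mode adds a `ZA:i:<span>` tag instead. A record
whose mate is absent from the file is only ever annotated, never removed,
because its pair geometry cannot be verified. The output header gains one
program-group line; all other records pass through byte-equivalent.

## Taxonomic profiling (`taxa_profile`)

BLAST tabular input is the standard 12-column dialect with an optional
13th `qlen` column (otherwise a read-length table must be supplied); query
coverage is `align_len / query_len`. Hits survive at coverage ≥ 0.80 and
e-value ≤ 1.0, both inclusive. Each query is assigned the species of its
best surviving hit — highest bitscore, ties broken by lowest e-value, then
lexicographic subject id — making assignment deterministic and
order-invariant. Queries with no surviving hit are `No-hit`; hits whose
subject is missing from the taxonomy table are reported separately as
`Unmapped-subject` rather than silently dropped.

Taxonomy is a user-supplied TSV (accession → species, genus, category over
the eleven fixed category labels), not a live database query, so runs are
reproducible offline. Category fractions are reported under **both**
denominators — all queries including `No-hit`, and assigned queries only —
because census tables in the literature are stated both ways.

Decoy selection applies two thresholds with different denominators, by
design: genera qualify at ≥ 0.001% of *all unaligned reads* (the richer
census of microbial diversity), while additional species qualify at ≥ 2%
of *positive (assigned) results* from the atypical-read census, skipping
species whose genus is already selected.

## Decoy construction (`decoy_build`)

Components are uppercased, IUPAC ambiguity codes collapse to N (lowercase
soft-masking is *not* treated as masked), and sequences are joined with
1000-N spacers; a component index maps any decoy coordinate back to its
source. Three mask passes then convert intervals to N. Masking is
length-preserving, idempotent, and commutative across passes (each pass
only writes N), which the tests verify directly.

**Human similarity.** The decoy is tiled with 100 bp windows every 50 bp.
A window is screened only if it shares an exact 12-mer with the human
sequence (the seed requirement); candidates are aligned as a whole into
the seeded human neighbourhood (infix alignment, edit-distance optimal,
via edlib) and masked when identity ≥ 0.65. Identity is defined as
`1 − edit_distance / window_length`. This edit-normalised definition was
chosen over matches-per-aligned-column deliberately: under the latter, a
gap-heavy optimal alignment of a window point-mutated to 60% identity can
exceed 0.65 (gaps reroute around mismatches and inflate the match
fraction), which contradicts the intent of a 65% screen. The tests verify
the screen against an independent full-DP glocal aligner (Biopython
`PairwiseAligner`). Window, step, seed length and threshold are all
parameters; only the 65% threshold is fixed by the method being modelled.

**Polynucleotide repeats** are interpreted as short-unit tandem repeats:
maximal runs where each base equals the base one unit earlier, unit length
1–6, total run ≥ 20 bp and at least two full units. Runs of N (the
spacers) are ignored. The interpretation (unit ≤ 6, total ≥ 20) is an
explicit design choice; both bounds are parameters.

**Internal duplicates** are exact repeats ≥ 100 bp found by chaining
consecutive shared 21-mers along diagonals; every copy *after the leftmost*
is masked and the first is retained, since masking all copies would delete
legitimate decoy content. k-mers occurring more than 64 times are skipped
(hyper-repetitive sequence is the tandem-repeat pass's job); this bounds
worst-case cost at the expense of pathological repeat families.

The finished decoy is appended to a reference FASTA as a new contig
(60-column wrapping, name-collision checked, indexable by `samtools
faidx`-compatible indexers).

## Impact quantification (`impact_report`)

Variants are matched on `(chrom, pos, ref, alt)` after multi-allelic
decomposition (each alt re-expressed as a bi-allelic genotype), without
left-normalisation — both callsets are assumed to come from one caller
pipeline. Classification is a partition: `lost` (pre only), `new` (post
only), `restored_hom_alt` (0/1 → 1/1), `unchanged`, `other`. The median
QUAL of lost variants uses the lower median so the statistic is always an
observed value. Distance from a variant to a cluster is measured from the
VCF POS to the nearest base of the cluster interval (0 inside), inclusive
at the 100 bp window; indels are anchored at POS only. Percent reductions
are `100 × (1 − post/pre)`, reported as undefined when `pre = 0` and
negative (with a warning, never clamped) when post exceeds pre. Allelic
support at a SNV classifies each overlapping primary read by the base its
CIGAR projects onto the locus, crossed with membership in the atypical
read-name set.

## Simulator (`simulate`) — what it emulates and what it does not

Defaults are the study conditions the package is designed around:
151 bp paired-end reads; typical inserts ~ Normal(400, 50) truncated above
the read length; atypical cores uniform on 19–25 bp with both mates
starting at the core position (symmetric geometry — real pairs can be
jittered, and planting positions/offsets are per-call arguments); MAPQ
drawn from bin weights 0.4541 / 0.1219 / 0.4240 for ≤ 10 / 11–39 / ≥ 40;
BLAST censuses with 32.86% no-hit queries and a bacteria-dominant
contaminant mixture (92.5% of assigned queries bacterial, with minor
plant/human/fungal/viral components); an unaligned-read pool of 7% of
reads; and a decoy that captures each atypical pair with probability
0.4366 and each unaligned read with probability 0.4484 (binomial
thinning). VCF fixtures plant 0/1→1/1 restorations, pre-only losses placed
within 100 bp of atypical cores, post-only gains and unchanged sites, with
lost-variant QUAL ~ Normal(45, 10) clipped positive.

Deliberately *not* modelled: sequencing errors and quality strings, aligner
scoring (MAPQ is assigned, not computed), real microbial sequence in read
flanks (random sequence by default), multi-contig references, and indel
variants. Passing tests therefore demonstrate the correctness of the
detection/selection/masking/classification logic under the stated
geometry, not aligner behaviour on real data — on real alignments the
span signature is the same, but MAPQ distributions, BLAST hit structure
and capture efficiency are properties of the data, not of this package.

All outputs are byte-identical across runs at a fixed seed; every emitted
read pair, BLAST query and variant locus has exactly one truth row.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at desk scale by choice:
planted-recovery uses 5,000 typical + 50 atypical pairs on a 200 kb
reference; the contaminant census uses 2,000 atypical pairs (≈ 1%
binomial error on census fractions); the genotype fixture uses a
10,000-variant callset. Oracle-equivalence checks run 100 seeded instances
per operation against brute-force implementations. Thresholds are applied
inclusively everywhere (span 30 in / 31 out; coverage 0.80 in / 0.79 out;
e-value 1.0 in / 1.01 out; distance 100 in / 101 out; genus frequency
0.001% in / 0.0009% out; species fraction 2.0% in / 1.9% out). Ties in
best-hit assignment and interval sorting are broken lexicographically;
empty inputs yield undefined (None) fractions rather than zeros.

## Known limitations

- The duplicate finder detects exact repeats only; diverged (inexact)
  internal duplications are not masked.
- The human-similarity screen requires an exact 12-mer seed; a window
  below ~70% identity with no 12-mer run is invisible to it, which is the
  usual seed-and-extend trade-off and irrelevant at the 65% threshold.
- Orphan records (mate missing from the file) can only be annotated, not
  removed, since their pair span cannot be verified.
- `compare_vcfs` assumes same-pipeline callsets; use the normalisation of
  your variant toolchain before comparing across pipelines.
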