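# Methods

## The model

A probe is a fixed-length oligo (default L = 25) expected to hybridise
to exactly one place in the transcriptome. The workflow decides, for
each probe, whether current references still support that expectation,
and then rebuilds each probe set around the probes that survive.

Reference databases are user-ranked. Rank 1 holds transcript catalogues
(typically two, e.g. RefSeq-like and Ensembl-like); rank 2 holds a
genomic assembly and/or an annotated nucleotide collection. Ranks are
processed in ascending order and **any resolution at a rank is
terminal**: a probe uniquely placed at rank 1 is never aligned at rank
2, and a probe discarded as a rank-1 multi-hit is not given a second
chance either (a configuration switch, `multi_hit_falls_through`,
enables the laxer reading). Additionally, probes belonging to a probe
set whose rank-1 evidence already reaches the retention threshold are
not carried into rank-2 mapping at all — their set is already decided,
and they are logged as lost to dominance.

### Alignment

Alignment is ungapped with a per-database mismatch cap *v* ∈ {0, 1, 2}
and best-stratum/all-hits reporting: all hits whose mismatch count
equals the minimum achievable for that probe in that database, and only
those. Defaults per database type: transcript *v* = 2 forward-only
(mismatches are later SNP-corrected); collection *v* = 0 forward-only
(no variant information exists for arbitrary collection entries, so
only exact matches are trustworthy); genomic *v* = 2 with reverse
complement allowed.

The implementation is exact by pigeonhole seeding: the probe is split
into *v* + 1 contiguous seeds (25/2 → 9, 8, 8), so every admissible
alignment contains at least one exact seed. All seed-length substrings
of every target are indexed as 2-bit integer codes in sorted arrays;
candidates found by binary search are verified base-by-base. Reverse
complement hits are reported in target-forward coordinates with strand
"−" and the probe bases complemented into that frame, giving a single
frame for projection and allele comparison. Ambiguity codes in targets
never match any probe base. An exhaustive numpy Hamming scan
(`brute_force_align`, guarded at 1 Mb) provides an independent oracle;
the test suite asserts set equality between the two on thousands of
random probes for every (v, strand) policy.

### Projection and SNP forgiveness

Transcript hits are projected through the transcript's exon chain
(0-based half-open intervals, transcription order) onto genomic blocks;
a junction-spanning probe yields one block per exon touched, and
minus-strand transcripts mirror coordinates. The footprint records
whether its chromosome is in the configured known-chromosome list.

A mismatch is forgiven iff a known SNV exists at its genomic position
and — in the default *strict* mode — the base the probe presents on the
genomic plus strand equals one of the recorded alleles. Both the
reference and the alternate alleles are accepted: a transcript sequence
may itself carry the alternate allele, in which case a probe matching
the reference is just as consistent with a real polymorphism. A
*relaxed* mode (`--relaxed-snp`) forgives at any recorded SNV position.
`effective_mm = raw_mm − |forgiven|`; only `effective_mm = 0` hits
("perfect" after correction) enter classification. The SNV count inside
each footprint's blocks is reported per probe for downstream filtering
(e.g. eQTL work).

### Classification

Within a rank, perfect hits are aggregated by identical genomic
footprint (chromosome, strand, exact block list): transcript variants
sharing the probe's exon collapse into one position carrying the union
of supporting (database, accession, symbol) entries. Collection hits
have no footprint and form pseudo-positions; when a genomic position
co-exists in the same rank they fold into it as supporting evidence,
otherwise they count among themselves.

At the first rank with any position: exactly one known-chromosome
position → specific at that rank; two or more known-chromosome
positions → unspecific (multi-hit). Scaffold positions never count
toward the multi-hit tally; a probe whose only position is on a
scaffold keeps it (flagged), while several scaffold-only positions are
unspecific with reason `ambiguous_scaffold` — nothing is removable by
the known-chromosome rule, but no unique position exists either. A
probe with alignments but no perfect position is unspecific
("imperfect"); a probe with no alignments anywhere is unaligned.

### Probe-set revision

Candidate **A** = the set's transcript-specific probes. Gene symbols
play the prominent role: a single shared symbol annotates A directly;
several symbols reduce A to the plurality symbol's probes (lexicographic
tie-break, conflict flagged); no symbols at all leave A anonymous but
intact. Candidate **B** = the genome-specific probes, partitioned into
collection groups (one per accession) and genomic-region clusters
(same chromosome and strand, gaps ≤ `cluster_gap`, default 100 kb — the
definition of "one region" is otherwise arbitrary, so it is an explicit
parameter); B is the single largest group, collection groups preferred
on ties because they carry curated annotation.

If |A| / n ≥ `retention_threshold` (default 0.5, "≥" inclusive so 10 of
20 passes), A wins outright. Otherwise the larger candidate wins, ties
prefer A. Statuses: `unchanged` (A = full initial set), `revised_rank1`,
`rank2`, `removed` (no candidate). A winner covering less than the
threshold is still retained by default with its retention fraction
reported; `--strict-threshold` removes such sets instead. The annotation
source of the winning symbol is categorised (both transcript databases >
first > second > collection+genomic > collection > anonymous genomic
region).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `probe_length` | 25 nt | platform probe length |
| `max_mismatches` (per DB) | 2 / 0 / 2 | mismatch cap: transcript / collection / genomic |
| `allow_reverse_complement` | genomic only | strand handling per database type |
| `retention_threshold` | 0.5 | fraction of initial probes candidate A needs to win outright |
| `cluster_gap` | 100 kb | max gap inside one genomic-region group of candidate B |
| `known_chromosomes` | config list | assembled chromosomes; multi-hit removal counts only these |
| `allele_strict` | true | SNP forgiveness requires an allele match |
| `multi_hit_falls_through` | false | whether a rank-1 multi-hit may still try rank 2 |

## The synthetic platform

The generator emulates a compact slice of a gene-ST array study: three
assembled chromosomes (140 kb each) plus two unplaced scaffolds of
random uniform-composition sequence; one gene per probe set (2–3 exons
of 120–250 nt, introns 80–300 nt, random strand), mirrored into two
rank-1 transcript databases under shared symbols, with 30 % of genes
carrying a variant transcript lacking the 5′ exon; ~1 background SNV per
gene; 200 probe sets of 15–27 probes. Probe fates are planted by
construction (exact substrings, one-mismatch copies with a matching
planted allele, junction-spanning windows, duplications into a decoy
transcript on another chromosome, intergenic genomic windows — one
orientation per set, since region clustering is strand-aware —
collection-only substrings, and verified-absent random sequences); the
fate mix is 45/15/10/8/10/7/5 % (clean/SNP/junction/multi/genomic/
collection/unmappable). Probe sets are drawn from four archetypes
(70 % mixed, 12 % purely transcript-specific, 10 % rank-2-dominant, 8 %
dead) so that every final status arises. The generator verifies each
plant by direct string comparison against the files it emits, and
writes truth tables for the expected per-probe class and per-probe-set
outcome; identical (spec, seed) pairs produce byte-identical files.

What the generator does **not** emulate: realistic base composition or
repeat structure (so seed indexes are less collision-prone than on real
genomes), sequencing error, population allele frequencies, 3′-biased
probe placement, and control/spiked-in probes (assumed stripped
upstream of the probe map). Passing planted-truth tests therefore
demonstrates the correctness of the decision logic under unambiguous
conditions, not recall on repeat-rich real references.

## Numerical and procedural choices

- All internal coordinates are 0-based half-open; GFF/GTF and VCF are
  converted at the read/write boundary exactly once.
- Output tables are canonically sorted (probe id / probe-set id), so a
  rerun on identical inputs is byte-identical; execution is serial and
  thread-count invariant (`--threads` is accepted for interface
  compatibility).
- Degenerate inputs: header-only probe maps yield an empty run with a
  warning; rows with wrong-length or non-ACGT sequences are rejected
  and counted (`invalid_sequence` in the discard log); duplicate probe
  ids and missing columns are fatal; transcripts with overlapping exons
  are dropped with a count; indel/multi-base VCF records are skipped
  with a count; a transcript/genomic database allowing mismatches
  without a variant file is a fatal configuration error.
- Indexing cost: the default study sizes (≈ 440 kb genome, ≈ 4 200
  probes, four databases) keep a full run in seconds on one core;
  larger references scale linearly in index size and probe count.

## Known limitations

- Gapped alignment and indel forgiveness are out of scope (probes are
  ungapped 25-mers); multi-nucleotide variants are skipped.
- Symbol conflict inside candidate A resolves by plurality rather than
  removing the set — least destructive deterministic rule; conflicts
  are flagged in the output.
- Collection entries receive no SNP correction (no coordinates to look
  up) and participate in position multiplicity only among themselves.
- The Venn partition counts perfect hits in the databases actually
  consulted for each probe; databases skipped by rank precedence do not
  contribute cells.
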