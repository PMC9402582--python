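"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open everywhere inside the package.
Readers convert from the native convention of each file format (GFF/GTF
and VCF are 1-based) exactly once, at parse time; writers convert back
exactly once, at serialisation time.

Strand conventions
------------------
An :class:`Alignment` is always expressed in the *target-forward* frame:
``target_start`` indexes the target's plus strand and every mismatch
records the base the probe presents on that strand (i.e. for a reverse
complement hit the probe base is already complemented).  This gives a
single coordinate frame for genomic projection and SNP lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# probe map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One fixed-length array probe and its initial probe-set membership."""

    probe_id: str
    probeset_id: str
    sequence: str  # uppercase, A/C/G/T only, platform probe length


@dataclass
class ProbeSetRecord:
    """A probe set: the group of probes summarised together on the array."""

    probeset_id: str
    probe_ids: list[str]

    @property
    def n_initial(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# reference databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentPolicy:
    """Ungapped alignment policy of one reference database.

    ``max_mismatches`` is the mismatch cap (``v`` in short-read-aligner
    terms); only the best stratum is ever reported, but all hits in it.
    """

    max_mismatches: int
    allow_reverse_complement: bool
    best_stratum_all_hits: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1, 2):
            raise ValueError(
                f"max_mismatches must be 0, 1 or 2, got {self.max_mismatches}")
        if not self.best_stratum_all_hits:
            raise ValueError("only best-stratum/all-hits reporting is supported")


#: db_type -> default policy.  Transcript databases tolerate two mismatches
#: (later corrected against known SNVs); sequence collections have no
#: variant information so demand exact matches; genomic databases tolerate
#: two mismatches and are the only ones searched on both strands.
DEFAULT_POLICIES = {
    "transcript": AlignmentPolicy(2, False),
    "collection": AlignmentPolicy(0, False),
    "genomic": AlignmentPolicy(2, True),
}

DB_TYPES = ("transcript", "genomic", "collection")


@dataclass
class ReferenceDB:
    """A named, ranked sequence database with its alignment policy."""

    name: str
    rank: int
    db_type: str  # transcript | genomic | collection
    sequences: dict[str, str]  # accession -> uppercase sequence
    policy: AlignmentPolicy
    symbols: dict[str, str] = field(default_factory=dict)  # accession -> gene symbol

    def __post_init__(self) -> None:
        if self.db_type not in DB_TYPES:
            raise ValueError(f"unknown db_type {self.db_type!r}")
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon chain of one transcript accession.

    ``exons`` are genomic half-open intervals sorted in transcription
    order: ascending genomic coordinate on '+', descending on '-'.
    """

    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    gene_symbol: Optional[str] = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    transcripts: dict[str, TranscriptModel]
    n_skipped_lines: int = 0
    n_dropped_transcripts: int = 0

    def get(self, transcript_id: str) -> Optional[TranscriptModel]:
        return self.transcripts.get(transcript_id)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_alleles: frozenset[str]

    @property
    def alleles(self) -> frozenset[str]:
        return self.alt_alleles | {self.ref_allele}


# ---------------------------------------------------------------------------
# alignment / projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mismatch:
    """A probe/target disagreement, in target-forward frame."""

    offset: int        # offset of the mismatch within the aligned window
    probe_base: str    # base the probe presents on the target plus strand
    target_base: str


@dataclass(frozen=True)
class Alignment:
    probe_id: str
    db_name: str
    target_id: str
    target_start: int
    strand_on_target: str  # '+' or '-'
    mismatches: tuple[Mismatch, ...]

    @property
    def raw_mm(self) -> int:
        return len(self.mismatches)

    def sort_key(self) -> tuple:
        return (self.target_id, self.target_start, self.strand_on_target)


@dataclass(frozen=True)
class GenomicFootprint:
    """Genomic blocks covered by one probe alignment.

    A probe lying inside a single exon (or aligned directly to the
    genome) yields one block; a junction-spanning probe yields one block
    per exon touched.  ``known_chromosome`` marks placement on an
    assembled chromosome as opposed to an unplaced scaffold.
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    known_chromosome: bool

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def key(self) -> tuple:
        return (self.chrom, self.strand, self.blocks)


@dataclass(frozen=True)
class CorrectedAlignment:
    """An alignment after SNP forgiveness.

    ``forgiven`` lists the window offsets of mismatches that coincide
    with a known SNV (allele-compatible in strict mode); ``effective_mm``
    is the raw mismatch count minus the forgiven ones.  Collection-type
    databases carry no genomic footprint and never receive forgiveness.
    """

    alignment: Alignment
    footprint: Optional[GenomicFootprint]
    forgiven: tuple[int, ...]
    n_snps_in_footprint: int

    @property
    def effective_mm(self) -> int:
        return self.alignment.raw_mm - len(self.forgiven)


# ---------------------------------------------------------------------------
# rank resolution
# ---------------------------------------------------------------------------

@dataclass
class AggregatedPosition:
    """One distinct mapping position of a probe within a rank.

    Alignments with byte-identical genomic footprints (e.g. transcript
    variants sharing the probe's exon) merge into one position; hits to
    collection databases have no footprint and form pseudo-positions
    keyed by (db, accession, offset, strand).
    """

    key: tuple
    footprint: Optional[GenomicFootprint]
    supporting: set[tuple]  # (db_name, target_id, gene_symbol or None)
    best_effective_mm: int
    n_snps_in_footprint: int = 0
    raw_mm: int = 0

    @property
    def is_pseudo(self) -> bool:
        return self.footprint is None


CLASS_RANK1 = "rank1_specific"
CLASS_RANK2 = "rank2_specific"
CLASS_UNSPECIFIC = "unspecific"
CLASS_UNALIGNED = "unaligned"


@dataclass
class ProbeClassification:
    probe_id: str
    cls: str
    rank: Optional[int] = None
    position: Optional[AggregatedPosition] = None
    db_provenance: frozenset[str] = frozenset()
    venn_key: tuple[str, ...] = ()
    reason: str = ""  # no_hit | imperfect | multi_hit | ambiguous_scaffold | ''

    @property
    def is_specific(self) -> bool:
        return self.cls in (CLASS_RANK1, CLASS_RANK2)


# ---------------------------------------------------------------------------
# probe-set assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyPolicy:
    retention_threshold: float = 0.5
    dominance_tie_break: str = "prefer_A"  # prefer_A | remove
    strict_threshold: bool = False  # remove sets whose winner covers < threshold
    cluster_gap: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.retention_threshold <= 1):
            raise ValueError("retention_threshold must be in (0, 1]")
        if self.dominance_tie_break not in ("prefer_A", "remove"):
            raise ValueError("dominance_tie_break must be prefer_A or remove")


STATUS_UNCHANGED = "unchanged"
STATUS_REVISED_RANK1 = "revised_rank1"
STATUS_RANK2 = "rank2"
STATUS_REMOVED = "removed"

SYMBOL_SOURCES = (
    "refseq_and_ensembl", "refseq", "ensembl", "nt_and_dna", "nt",
    "dna_region", "none",
)


@dataclass
class Candidate:
    """A candidate revised probe set (rank-1 'A' or rank-2 'B')."""

    kind: str  # 'A' or 'B'
    probe_ids: list[str]
    gene_symbol: Optional[str]
    source_dbs: frozenset[str]
    span: Optional[GenomicFootprint]
    symbol_conflict: bool = False
    group_label: str = ""  # B only: 'nt' or 'dna_region'

    @property
    def size(self) -> int:
        return len(self.probe_ids)


@dataclass
class RevisedProbeSet:
    probeset_id: str
    status: str
    retained_probe_ids: list[str]
    n_initial: int
    gene_symbol: Optional[str]
    symbol_source: str
    span: Optional[GenomicFootprint]
    symbol_conflict: bool = False

    @property
    def n_retained(self) -> int:
        return len(self.retained_probe_ids)

    @property
    def retention_fraction(self) -> float:
        return self.n_retained / self.n_initial if self.n_initial else 0.0


# discard reason codes (one per probe not in a retained probe set)
REASON_NO_HIT = "no_hit"
REASON_MULTI_HIT = "multi_hit"
REASON_LOST = "lost_to_dominance"
REASON_SET_REMOVED = "set_removed"
REASON_INVALID = "invalid_sequence"
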