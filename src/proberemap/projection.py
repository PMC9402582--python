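"""Transcript-to-genome projection, SNP forgiveness and SNP counting.

A probe aligned to a transcript is projected through the transcript's
exon chain onto genomic blocks; mismatches are then looked up at their
genomic positions in the known-variant index, and a mismatch coinciding
with a known SNV is "forgiven" (it no longer counts against the probe).
In the default *strict* mode the base the probe presents on the genomic
plus strand must equal one of the recorded alleles (reference or
alternate); the relaxed mode forgives at any known SNV position.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Iterable, Optional

from .models import (Alignment, CorrectedAlignment, GenomicFootprint,
                     SNPRecord, TranscriptModel, complement_base)

__all__ = ["SnpIndex", "project_to_genome", "genomic_footprint_of_hit",
           "transcript_pos_to_genome", "correct_snps", "count_snps",
           "UnprojectableAlignment"]

# NOTE: transcript hits keep mismatch offsets in transcript coordinates;
# correct_snps projects each offset individually before allele lookup.


class UnprojectableAlignment(Exception):
    """Raised when a transcript hit has no usable gene-model entry."""


class SnpIndex:
    """Chromosome-indexed SNV lookup: O(1) by site, O(log n) by interval."""

    def __init__(self, records: Iterable[SNPRecord]):
        self._by_site: dict[tuple[str, int], SNPRecord] = {}
        self._positions: dict[str, list[int]] = {}
        for rec in records:
            key = (rec.chrom, rec.pos)
            prev = self._by_site.get(key)
            if prev is not None:
                rec = SNPRecord(rec.chrom, rec.pos, prev.ref_allele,
                                prev.alt_alleles | rec.alt_alleles)
            self._by_site[key] = rec
        for chrom, pos in self._by_site:
            self._positions.setdefault(chrom, []).append(pos)
        for chrom in self._positions:
            self._positions[chrom].sort()

    def __len__(self) -> int:
        return len(self._by_site)

    def at(self, chrom: str, pos: int) -> Optional[SNPRecord]:
        return self._by_site.get((chrom, pos))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of SNVs with start <= pos < end on ``chrom``."""
        positions = self._positions.get(chrom)
        if not positions:
            return 0
        return bisect_left(positions, end) - bisect_left(positions, start)

    def records(self) -> list[SNPRecord]:
        return sorted(self._by_site.values(), key=lambda r: (r.chrom, r.pos))


def _transcript_spans(model: TranscriptModel) -> list[tuple[int, int]]:
    """Cumulative transcript-coordinate span [ts, te) of each exon."""
    spans, off = [], 0
    for s, e in model.exons:
        spans.append((off, off + (e - s)))
        off += e - s
    return spans


def transcript_pos_to_genome(model: TranscriptModel, tpos: int) -> int:
    """Genomic coordinate of transcript position ``tpos``."""
    if tpos < 0 or tpos >= model.length:
        raise ValueError(f"transcript position {tpos} outside [0, {model.length})")
    for (s, e), (ts, te) in zip(model.exons, _transcript_spans(model)):
        if ts <= tpos < te:
            if model.strand == "+":
                return s + (tpos - ts)
            return e - 1 - (tpos - ts)
    raise AssertionError("unreachable")


def genomic_footprint_of_hit(aln: Alignment, probe_length: int,
                             known_chromosomes: frozenset[str]) -> GenomicFootprint:
    """Footprint of a direct genomic-database hit: one block on the target."""
    block = (aln.target_start, aln.target_start + probe_length)
    return GenomicFootprint(aln.target_id, aln.strand_on_target, (block,),
                            aln.target_id in known_chromosomes)


def project_to_genome(aln: Alignment, probe_length: int,
                      model: TranscriptModel,
                      known_chromosomes: frozenset[str]) -> GenomicFootprint:
    """Genomic blocks covered by a transcript-space alignment.

    A probe spanning an exon junction yields one block per exon touched;
    blocks are reported sorted by genomic coordinate.  The footprint
    strand combines the transcript's genomic strand with the hit's
    orientation on the transcript.
    """
    t0 = aln.target_start
    t1 = t0 + probe_length
    if t1 > model.length:
        raise ValueError(
            f"alignment [{t0}, {t1}) extends past transcript "
            f"{model.transcript_id} of length {model.length}")
    blocks = []
    for (s, e), (ts, te) in zip(model.exons, _transcript_spans(model)):
        o0, o1 = max(t0, ts), min(t1, te)
        if o0 >= o1:
            continue
        if model.strand == "+":
            blocks.append((s + (o0 - ts), s + (o1 - ts)))
        else:
            blocks.append((e - (o1 - ts), e - (o0 - ts)))
    blocks.sort()
    strand = model.strand if aln.strand_on_target == "+" else (
        "-" if model.strand == "+" else "+")
    assert sum(b - a for a, b in blocks) == probe_length
    return GenomicFootprint(model.chrom, strand, tuple(blocks),
                            model.chrom in known_chromosomes)


def correct_snps(aln: Alignment, footprint: GenomicFootprint,
                 snps: SnpIndex, *, allele_strict: bool = True,
                 model: Optional[TranscriptModel] = None) -> CorrectedAlignment:
    """Forgive mismatches that coincide with known SNVs.

    For transcript hits, each mismatch offset is projected through the
    exon chain (``model`` required); the probe base is complemented into
    the genomic plus frame for minus-strand transcripts before allele
    comparison.  Direct genomic hits are already in the plus frame.
    """
    forgiven = []
    for mm in aln.mismatches:
        if model is not None:
            gpos = transcript_pos_to_genome(model, aln.target_start + mm.offset)
            probe_base = (mm.probe_base if model.strand == "+"
                          else complement_base(mm.probe_base))
        else:
            gpos = aln.target_start + mm.offset
            probe_base = mm.probe_base
        rec = snps.at(footprint.chrom, gpos)
        if rec is None:
            continue
        if allele_strict and probe_base not in rec.alleles:
            continue
        forgiven.append(mm.offset)
    n_snps = count_snps(footprint, snps)
    return CorrectedAlignment(aln, footprint, tuple(forgiven), n_snps)


def count_snps(footprint: GenomicFootprint, snps: SnpIndex) -> int:
    """Known SNVs falling inside the footprint's blocks (half-open)."""
    return sum(snps.count_in(footprint.chrom, s, e) for s, e in footprint.blocks)
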