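"""Combine per-database hits into one verdict per probe.

Ranks are processed in ascending order.  Within a rank, SNP-corrected
perfect hits (effective mismatches = 0) are aggregated by genomic
position, so transcript variants sharing the probe's exon collapse into
a single position.  A probe resolving to exactly one position on a
known chromosome at the first productive rank is *specific* at that
rank; two or more known-chromosome positions make it *unspecific*
(multi-hit) and — because any resolution at a rank terminates
processing — lower-priority ranks are not consulted.  Unplaced-scaffold
positions never count toward the multi-hit tally, but a probe whose
only position sits on a scaffold keeps that position.

Hits to collection databases (no genomic footprint) form
pseudo-positions.  When a genomic position exists in the same rank,
collection hits fold into it as supporting evidence; on their own they
participate in multiplicity among themselves.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional

from .models import (CLASS_RANK1, CLASS_RANK2, CLASS_UNALIGNED,
                     CLASS_UNSPECIFIC, AggregatedPosition, CorrectedAlignment,
                     ProbeClassification)

__all__ = ["aggregate_positions", "classify_probe", "resolve_rank", "venn_partition"]


def aggregate_positions(corrected: Iterable[CorrectedAlignment],
                        symbol_of: Optional[dict] = None) -> list[AggregatedPosition]:
    """Merge perfect hits of one probe (one rank) by genomic position.

    ``symbol_of`` maps (db_name, target_id) to a gene symbol when one is
    known.  Hits with byte-identical footprints merge; footprint-less
    collection hits each form their own pseudo-position.
    """
    positions: dict[tuple, AggregatedPosition] = {}
    for ca in corrected:
        if ca.effective_mm != 0:
            raise ValueError("aggregate_positions expects perfect hits only")
        aln = ca.alignment
        symbol = None
        if symbol_of is not None:
            symbol = symbol_of.get((aln.db_name, aln.target_id))
        entry = (aln.db_name, aln.target_id, symbol)
        if ca.footprint is not None:
            key = ("genomic",) + ca.footprint.key()
        else:
            key = ("pseudo", aln.db_name, aln.target_id, aln.target_start,
                   aln.strand_on_target)
        pos = positions.get(key)
        if pos is None:
            positions[key] = AggregatedPosition(
                key=key, footprint=ca.footprint, supporting={entry},
                best_effective_mm=0,
                n_snps_in_footprint=ca.n_snps_in_footprint,
                raw_mm=aln.raw_mm)
        else:
            pos.supporting.add(entry)
            pos.raw_mm = min(pos.raw_mm, aln.raw_mm)
    return sorted(positions.values(), key=lambda p: p.key)


def resolve_rank(positions: list[AggregatedPosition]):
    """Outcome of one rank: ('specific', pos) | ('multi', reason) | None."""
    genomic = [p for p in positions if not p.is_pseudo]
    pseudo = [p for p in positions if p.is_pseudo]
    if not genomic and not pseudo:
        return None
    known = [p for p in genomic if p.footprint.known_chromosome]
    scaffold = [p for p in genomic if not p.footprint.known_chromosome]
    if len(known) >= 2:
        return ("multi", "multi_hit")
    if len(known) == 1:
        pos = known[0]
        for p in pseudo:  # collection hits support the genomic position
            pos.supporting |= p.supporting
        return ("specific", pos)
    if scaffold:
        if len(scaffold) == 1:
            pos = scaffold[0]
            for p in pseudo:
                pos.supporting |= p.supporting
            return ("specific", pos)
        # several scaffold-only placements: none is removable by the
        # known-chromosome rule, but no unique position exists either
        return ("multi", "ambiguous_scaffold")
    # collection pseudo-positions only
    if len(pseudo) == 1:
        return ("specific", pseudo[0])
    return ("multi", "multi_hit")


def classify_probe(probe_id: str,
                   per_rank_positions: Mapping[int, list[AggregatedPosition]],
                   *, had_any_alignment: bool = True,
                   multi_hit_falls_through: bool = False) -> ProbeClassification:
    """One verdict per probe from its per-rank aggregated perfect hits.

    ``had_any_alignment`` distinguishes probes with imperfect hits only
    (unspecific) from probes that never aligned at all (unaligned).
    ``multi_hit_falls_through`` optionally lets a probe that is
    multi-hit at one rank still try lower-priority ranks.
    """
    last_multi_reason = ""
    for rank in sorted(per_rank_positions):
        outcome = resolve_rank(per_rank_positions[rank])
        if outcome is None:
            continue
        kind, payload = outcome
        if kind == "specific":
            pos = payload
            dbs = frozenset(e[0] for e in pos.supporting)
            cls = CLASS_RANK1 if rank == 1 else CLASS_RANK2
            return ProbeClassification(probe_id, cls, rank=rank, position=pos,
                                       db_provenance=dbs)
        if not multi_hit_falls_through:
            return ProbeClassification(probe_id, CLASS_UNSPECIFIC, rank=rank,
                                       reason=payload)
        last_multi_reason = payload
    if last_multi_reason:
        return ProbeClassification(probe_id, CLASS_UNSPECIFIC,
                                   reason=last_multi_reason)
    if had_any_alignment:
        return ProbeClassification(probe_id, CLASS_UNSPECIFIC, reason="imperfect")
    return ProbeClassification(probe_id, CLASS_UNALIGNED, reason="no_hit")


def venn_partition(classifications: Iterable[ProbeClassification]
                   ) -> dict[tuple[str, ...], int]:
    """Probe counts keyed by the exact set of databases with a perfect hit.

    Probes without any perfect hit do not appear; the cell counts
    therefore sum to the number of probes with at least one perfect hit.
    """
    counter: Counter[tuple[str, ...]] = Counter()
    for cl in classifications:
        if cl.venn_key:
            counter[tuple(sorted(cl.venn_key))] += 1
    return dict(counter)
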