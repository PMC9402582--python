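"""Per-probe-set revision: candidates A/B, retention rule and dominance.

Each initial probe set is revised independently:

* **Candidate A** gathers the set's transcript-specific (rank-1)
  probes.  Gene symbols attached to their aggregated positions play the
  prominent role: if all positions agree on a single symbol, A carries
  it; if several symbols occur, A restricts to the probes of the
  plurality symbol (lexicographic tie-break, conflict recorded); if no
  position carries any symbol, A keeps all rank-1 probes with the
  symbol absent.

* **Candidate B** gathers the genome-specific (rank-2) probes and
  partitions them into collection-annotated groups (one per collection
  accession) and genomic-region groups (footprints on one chromosome
  and strand clustered with gaps up to ``cluster_gap``).  The single
  largest group becomes B.

* If A covers at least the retention threshold (default 50%) of the
  probes initially assigned to the set, A wins outright and rank-2
  evidence is not consulted.  Otherwise the larger of A and B dominates
  (ties prefer A, which carries curated annotation).  A set with no
  candidate at all is removed.

By default a winner covering less than the threshold still yields a
retained probe set (its retention fraction is reported); a strict mode
removes such sets instead.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Optional

from .models import (CLASS_RANK1, CLASS_RANK2, STATUS_RANK2, STATUS_REMOVED,
                     STATUS_REVISED_RANK1, STATUS_UNCHANGED, AssemblyPolicy,
                     Candidate, GenomicFootprint, ProbeClassification,
                     ProbeSetRecord, RevisedProbeSet)

__all__ = ["build_candidate_A", "build_candidate_B", "assemble",
           "resolve_symbol_source"]


def _span_of(footprints: list[GenomicFootprint]) -> Optional[GenomicFootprint]:
    """Merged single-block span of same-chromosome footprints (else None)."""
    fps = [f for f in footprints if f is not None]
    if not fps:
        return None
    chroms = {f.chrom for f in fps}
    strands = {f.strand for f in fps}
    if len(chroms) > 1:
        return None
    start = min(f.start for f in fps)
    end = max(f.end for f in fps)
    strand = strands.pop() if len(strands) == 1 else "+"
    return GenomicFootprint(chroms.pop(), strand, ((start, end),),
                            fps[0].known_chromosome)


def build_candidate_A(ps: ProbeSetRecord,
                      classifications: Mapping[str, ProbeClassification]
                      ) -> Optional[Candidate]:
    """Rank-1 candidate of one probe set, or None if no rank-1 probes."""
    rank1 = [(pid, classifications[pid]) for pid in ps.probe_ids
             if classifications[pid].cls == CLASS_RANK1]
    if not rank1:
        return None
    probe_symbols: dict[str, set[str]] = {}
    probe_sources: dict[str, set[str]] = {}
    for pid, cl in rank1:
        syms, srcs = set(), set()
        for db_name, _target, symbol in cl.position.supporting:
            srcs.add(db_name)
            if symbol is not None:
                syms.add(symbol)
        probe_symbols[pid] = syms
        probe_sources[pid] = srcs
    all_symbols = set().union(*probe_symbols.values())
    if not all_symbols:
        kept = [pid for pid, _ in rank1]
        symbol, conflict = None, False
    else:
        votes: dict[str, int] = defaultdict(int)
        for pid, _ in rank1:
            for sym in probe_symbols[pid]:
                votes[sym] += 1
        best = max(votes.values())
        symbol = min(s for s, v in votes.items() if v == best)
        kept = [pid for pid, _ in rank1 if symbol in probe_symbols[pid]]
        conflict = len(all_symbols) > 1
    source_dbs = frozenset().union(
        *(probe_sources[pid] for pid in kept)) if kept else frozenset()
    span = _span_of([classifications[pid].position.footprint for pid in kept])
    return Candidate("A", kept, symbol, source_dbs, span,
                     symbol_conflict=conflict)


def _cluster_regions(items: list[tuple[str, GenomicFootprint]],
                     gap: int) -> list[list[str]]:
    """Group probe ids whose footprints sit on one chrom/strand within gap."""
    by_cs: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for pid, fp in items:
        by_cs[(fp.chrom, fp.strand)].append((fp.start, fp.end, pid))
    clusters = []
    for key in sorted(by_cs):
        entries = sorted(by_cs[key])
        current: list[str] = []
        last_end = None
        for start, end, pid in entries:
            if last_end is not None and start - last_end > gap:
                clusters.append(current)
                current = []
            current.append(pid)
            last_end = end if last_end is None else max(last_end, end)
        if current:
            clusters.append(current)
    return clusters


def build_candidate_B(ps: ProbeSetRecord,
                      classifications: Mapping[str, ProbeClassification],
                      policy: AssemblyPolicy) -> Optional[Candidate]:
    """Rank-2 candidate: the largest collection or genomic-region group."""
    rank2 = [(pid, classifications[pid]) for pid in ps.probe_ids
             if classifications[pid].cls == CLASS_RANK2]
    if not rank2:
        return None
    nt_groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    nt_symbols: dict[tuple[str, str], Optional[str]] = {}
    genomic_items: list[tuple[str, GenomicFootprint]] = []
    for pid, cl in rank2:
        if cl.position.is_pseudo:
            db_name, target_id, symbol = sorted(cl.position.supporting)[0]
            nt_groups[(db_name, target_id)].append(pid)
            nt_symbols[(db_name, target_id)] = symbol
        else:
            genomic_items.append((pid, cl.position.footprint))
    candidates: list[tuple[int, int, str, Candidate]] = []
    for key in sorted(nt_groups):
        pids = nt_groups[key]
        cand = Candidate("B", pids, nt_symbols[key],
                         frozenset(d for p in pids
                                   for d, _, _ in classifications[p].position.supporting),
                         None, group_label="nt")
        # rank for dominance: size desc, collection groups preferred on ties
        candidates.append((len(pids), 1, key[1], cand))
    for cluster in _cluster_regions(genomic_items, policy.cluster_gap):
        fps = [classifications[p].position.footprint for p in cluster]
        span = _span_of(fps)
        dbs = frozenset(d for p in cluster
                        for d, _, _ in classifications[p].position.supporting)
        cand = Candidate("B", cluster, None, dbs, span, group_label="dna_region")
        candidates.append((len(cluster), 0, cluster[0], cand))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return candidates[0][3]


def assemble(ps: ProbeSetRecord, candidate_A: Optional[Candidate],
             candidate_B: Optional[Candidate],
             policy: AssemblyPolicy,
             db_types: Optional[Mapping[str, str]] = None) -> RevisedProbeSet:
    """Apply the retention threshold and A/B dominance to one probe set."""
    n = ps.n_initial
    size_a = candidate_A.size if candidate_A else 0
    size_b = candidate_B.size if candidate_B else 0
    winner: Optional[Candidate] = None
    if size_a and size_a / n >= policy.retention_threshold:
        winner = candidate_A
    elif size_a or size_b:
        if size_a > size_b:
            winner = candidate_A
        elif size_b > size_a:
            winner = candidate_B
        else:  # tie
            winner = candidate_A if policy.dominance_tie_break == "prefer_A" else None
    if winner is None:
        return RevisedProbeSet(ps.probeset_id, STATUS_REMOVED, [], n, None,
                               "none", None)
    if policy.strict_threshold and winner.size / n < policy.retention_threshold:
        return RevisedProbeSet(ps.probeset_id, STATUS_REMOVED, [], n, None,
                               "none", None)
    if winner.kind == "A":
        status = (STATUS_UNCHANGED if winner.size == n else STATUS_REVISED_RANK1)
    else:
        status = STATUS_RANK2
    source = resolve_symbol_source(winner, db_types or {})
    return RevisedProbeSet(ps.probeset_id, status, list(winner.probe_ids), n,
                           winner.gene_symbol, source, winner.span,
                           symbol_conflict=winner.symbol_conflict)


# canonical names by which the annotation-source categories are keyed when
# the configured databases use them (case-insensitive)
_CANON_RANK1 = ("refseq", "ensembl")


def resolve_symbol_source(candidate: Candidate,
                          db_types: Mapping[str, str]) -> str:
    """Annotation-source category of the winning candidate.

    Rank-1 sources follow the priority both-transcript-databases >
    first > second; rank-2 follows collection-plus-genomic > collection
    > genomic region.  Databases named ``refseq``/``ensembl``/``nt``/
    ``dna`` (case-insensitive) map onto the canonical category names;
    other names are joined verbatim.
    """
    names = sorted(n.lower() for n in candidate.source_dbs)
    if candidate.kind == "A":
        r1 = [n for n in names if db_types.get(n, "transcript") == "transcript"
              or n in _CANON_RANK1]
        if set(_CANON_RANK1) <= set(r1):
            return "refseq_and_ensembl"
        if r1 == ["refseq"]:
            return "refseq"
        if r1 == ["ensembl"]:
            return "ensembl"
        if candidate.gene_symbol is None:
            return "none"
        return "+".join(r1) if r1 else "none"
    # candidate B
    has_collection = any(db_types.get(n, "") == "collection" or n == "nt"
                         for n in names)
    has_genomic = any(db_types.get(n, "") == "genomic" or n == "dna"
                      for n in names)
    if candidate.group_label == "nt":
        return "nt_and_dna" if has_genomic else "nt"
    if has_collection:
        return "nt_and_dna"
    return "dna_region"
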