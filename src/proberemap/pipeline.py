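"""End-to-end driver: align, correct, classify, assemble, report.

The run is fully deterministic: given identical inputs and
configuration, the output tables are byte-identical.  Probes are
processed rank by rank; any probe resolved at a rank (uniquely placed
or discarded as a multi-hit) is excluded from lower-priority ranks.
After the first rank, probe sets whose transcript-specific probes
already reach the retention threshold short-circuit: their remaining
probes are discarded rather than carried into rank-2 mapping, matching
the per-probe-set algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import assembly as asm
from . import io as pio
from .aligner import align_probe, build_index
from .models import (CLASS_RANK1, CLASS_RANK2, CLASS_UNALIGNED,
                     CLASS_UNSPECIFIC, REASON_INVALID, REASON_LOST,
                     REASON_MULTI_HIT, REASON_NO_HIT, REASON_SET_REMOVED,
                     STATUS_REMOVED, CorrectedAlignment, ProbeClassification,
                     ProbeRecord, ReferenceDB, RevisedProbeSet)
from .projection import (SnpIndex, correct_snps, genomic_footprint_of_hit,
                         project_to_genome)
from .ranking import aggregate_positions, classify_probe, resolve_rank, venn_partition

__all__ = ["run_pipeline", "PipelineResult", "RunSummary", "render_report"]


@dataclass
class RunSummary:
    """Aggregate numbers of one run; all identities are checkable."""

    total_probes: int
    n_rejected_rows: int
    class_counts: dict[str, int]
    venn: dict[str, int]  # '+'-joined db names -> probe count
    probeset_status_counts: dict[str, int]
    symbol_source_counts: dict[str, int]
    n_probesets_initial: int
    n_probes_retained: int
    fraction_probes_best_choice: float
    n_probesets_half_retained: int  # sets whose winner covers >= threshold
    n_unique_genes: int
    snps_per_probe_hist: dict[str, int]

    def check(self) -> None:
        if sum(self.class_counts.values()) != self.total_probes:
            raise AssertionError("probe classes do not partition the probes")
        if sum(self.probeset_status_counts.values()) != self.n_probesets_initial:
            raise AssertionError("statuses do not partition the probe sets")
        n_perfect = sum(self.venn.values())
        n_specific = (self.class_counts.get(CLASS_RANK1, 0)
                      + self.class_counts.get(CLASS_RANK2, 0))
        if n_perfect < n_specific:
            raise AssertionError("fewer perfect-hit probes than specific probes")

    def to_dict(self) -> dict:
        return {
            "total_probes": self.total_probes,
            "n_rejected_rows": self.n_rejected_rows,
            "class_counts": dict(sorted(self.class_counts.items())),
            "venn": dict(sorted(self.venn.items())),
            "probeset_status_counts": dict(sorted(self.probeset_status_counts.items())),
            "symbol_source_counts": dict(sorted(self.symbol_source_counts.items())),
            "n_probesets_initial": self.n_probesets_initial,
            "n_probes_retained": self.n_probes_retained,
            "fraction_probes_best_choice": self.fraction_probes_best_choice,
            "n_probesets_half_retained": self.n_probesets_half_retained,
            "n_unique_genes": self.n_unique_genes,
            "snps_per_probe_hist": dict(sorted(self.snps_per_probe_hist.items())),
        }


@dataclass
class PipelineResult:
    classifications: dict[str, ProbeClassification]
    revised: dict[str, RevisedProbeSet]
    probe_rows: list[dict]
    probeset_rows: list[dict]
    discard_rows: list[dict]
    summary: RunSummary


def _correct_alignment(aln, db: ReferenceDB, cfg: pio.RunConfig, gene_model,
                       snps: SnpIndex, known: frozenset[str]
                       ) -> Optional[CorrectedAlignment]:
    """SNP-corrected alignment, or None when the hit cannot be projected."""
    if db.db_type == "collection":
        return CorrectedAlignment(aln, None, (), 0)
    if db.db_type == "genomic":
        fp = genomic_footprint_of_hit(aln, cfg.probe_length, known)
        return correct_snps(aln, fp, snps, allele_strict=cfg.allele_strict)
    model = gene_model.get(aln.target_id) if gene_model else None
    if model is None:
        return None  # unprojectable: transcript absent from the gene model
    fp = project_to_genome(aln, cfg.probe_length, model, known)
    return correct_snps(aln, fp, snps, allele_strict=cfg.allele_strict,
                        model=model)


def run_pipeline(cfg: pio.RunConfig, out_dir: Optional[str | Path] = None,
                 threads: int = 1) -> PipelineResult:
    """Execute the full revision workflow described in the module docstring.

    ``threads`` is accepted for interface compatibility; execution is
    serial and results are therefore trivially thread-count invariant.
    """
    if threads < 1:
        raise pio.ConfigError("threads must be >= 1")
    probe_map = pio.read_probe_map(cfg.probe_map, cfg.probe_length)
    gene_model = pio.read_gene_model(cfg.gene_model) if cfg.gene_model else None
    snps = (pio.read_snvs(cfg.variants).index if cfg.variants
            and Path(cfg.variants).exists() else SnpIndex([]))
    known = frozenset(cfg.known_chromosomes)
    dbs = [pio.load_reference_db(d) for d in cfg.databases]
    by_rank: dict[int, list[ReferenceDB]] = {}
    for db in dbs:
        by_rank.setdefault(db.rank, []).append(db)
    symbol_of: dict[tuple[str, str], str] = {}
    for db in dbs:
        if db.db_type == "transcript" and gene_model is not None:
            for acc in db.sequences:
                tm = gene_model.get(acc)
                if tm is not None and tm.gene_symbol:
                    symbol_of[(db.name, acc)] = tm.gene_symbol
        for acc, sym in db.symbols.items():
            symbol_of[(db.name, acc)] = sym
    _validate_transcript_lengths(dbs, gene_model)

    probes_by_set: dict[str, list[ProbeRecord]] = {}
    for p in probe_map.probes:
        probes_by_set.setdefault(p.probeset_id, []).append(p)

    per_rank_positions: dict[str, dict[int, list]] = {p.probe_id: {}
                                                     for p in probe_map.probes}
    had_alignment: dict[str, bool] = {p.probe_id: False for p in probe_map.probes}
    venn_dbs: dict[str, set[str]] = {p.probe_id: set() for p in probe_map.probes}
    shortcut_lost: set[str] = set()

    active: list[ProbeRecord] = list(probe_map.probes)
    ranks = sorted(by_rank)
    for rank_i, rank in enumerate(ranks):
        indexes = [(db, build_index(db, cfg.probe_length)) for db in by_rank[rank]]
        next_active: list[ProbeRecord] = []
        for probe in active:
            perfect: list[CorrectedAlignment] = []
            for db, index in indexes:
                for aln in align_probe(probe, index):
                    had_alignment[probe.probe_id] = True
                    ca = _correct_alignment(aln, db, cfg, gene_model, snps, known)
                    if ca is not None and ca.effective_mm == 0:
                        perfect.append(ca)
                        venn_dbs[probe.probe_id].add(db.name)
            positions = aggregate_positions(perfect, symbol_of)
            per_rank_positions[probe.probe_id][rank] = positions
            outcome = resolve_rank(positions)
            if outcome is None:
                next_active.append(probe)
            elif outcome[0] == "multi" and cfg.multi_hit_falls_through:
                next_active.append(probe)
        # probe sets already satisfied at the first rank do not carry
        # their unresolved probes into lower-priority ranks
        if rank_i == 0 and len(ranks) > 1:
            still_active = []
            for probe in next_active:
                mates = probes_by_set[probe.probeset_id]
                n_resolved = sum(
                    1 for m in mates
                    if (out := resolve_rank(
                        per_rank_positions[m.probe_id].get(rank, []))) is not None
                    and out[0] == "specific")
                if n_resolved / len(mates) >= cfg.retention_threshold:
                    shortcut_lost.add(probe.probe_id)
                else:
                    still_active.append(probe)
            next_active = still_active
        active = next_active

    classifications: dict[str, ProbeClassification] = {}
    for p in probe_map.probes:
        cl = classify_probe(p.probe_id, per_rank_positions[p.probe_id],
                            had_any_alignment=had_alignment[p.probe_id],
                            multi_hit_falls_through=cfg.multi_hit_falls_through)
        cl.venn_key = tuple(sorted(venn_dbs[p.probe_id]))
        classifications[p.probe_id] = cl

    policy = cfg.assembly_policy()
    db_types = {db.name.lower(): db.db_type for db in dbs}
    revised: dict[str, RevisedProbeSet] = {}
    for ps in probe_map.probesets:
        cand_a = asm.build_candidate_A(ps, classifications)
        size_a = cand_a.size if cand_a else 0
        cand_b = None
        if not (size_a and size_a / ps.n_initial >= policy.retention_threshold):
            cand_b = asm.build_candidate_B(ps, classifications, policy)
        revised[ps.probeset_id] = asm.assemble(ps, cand_a, cand_b, policy, db_types)

    probe_rows, discard_rows = _probe_rows(probe_map, classifications, revised,
                                           shortcut_lost)
    probeset_rows = _probeset_rows(revised)
    summary = _summarize(probe_map, classifications, revised, policy)
    result = PipelineResult(classifications, revised, probe_rows,
                            probeset_rows, discard_rows, summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_probe_table(probe_rows, out_dir / "probe_table.tsv")
        pio.write_probeset_table(probeset_rows, out_dir / "probeset_table.tsv")
        pio.write_discard_log(discard_rows, out_dir / "discard_log.tsv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "report.txt", "w") as fh:
            fh.write(render_report(summary))
    return result


def _validate_transcript_lengths(dbs, gene_model) -> None:
    if gene_model is None:
        return
    for db in dbs:
        if db.db_type != "transcript":
            continue
        covered = 0
        for acc, seq in db.sequences.items():
            tm = gene_model.get(acc)
            if tm is None:
                continue
            covered += 1
            if tm.length != len(seq):
                raise pio.ConfigError(
                    f"transcript {acc}: exon chain length {tm.length} != "
                    f"sequence length {len(seq)}")
        if covered == 0:
            raise pio.ConfigError(
                f"transcript database {db.name!r}: gene model covers none of "
                f"its accessions")


def _probe_rows(probe_map, classifications, revised, shortcut_lost):
    rows, discards = [], []
    retained_by_set = {psid: set(r.retained_probe_ids)
                       for psid, r in revised.items()}
    for p in probe_map.probes:
        cl = classifications[p.probe_id]
        rset = revised[p.probeset_id]
        in_revised = p.probe_id in retained_by_set[p.probeset_id]
        row = {c: "" for c in pio.PROBE_TABLE_COLUMNS}
        row["probe_id"] = p.probe_id
        row["probeset_id_initial"] = p.probeset_id
        row["probeset_id_revised"] = p.probeset_id if in_revised else ""
        row["class"] = cl.cls
        row["rank"] = cl.rank if cl.rank is not None else ""
        row["db_names"] = ",".join(sorted(cl.db_provenance))
        if cl.position is not None and cl.position.footprint is not None:
            fp = cl.position.footprint
            row.update(chrom=fp.chrom, strand=fp.strand, start=fp.start,
                       end=fp.end,
                       blocks=",".join(f"{s}-{e}" for s, e in fp.blocks),
                       raw_mismatches=cl.position.raw_mm,
                       effective_mismatches=0,
                       n_snps_in_footprint=cl.position.n_snps_in_footprint)
        elif cl.position is not None:  # collection pseudo-position
            row.update(raw_mismatches=cl.position.raw_mm, effective_mismatches=0,
                       n_snps_in_footprint=0)
        rows.append(row)
        if not in_revised:
            if cl.cls == CLASS_UNALIGNED:
                reason = REASON_NO_HIT
            elif cl.cls == CLASS_UNSPECIFIC:
                reason = (REASON_NO_HIT if cl.reason == "imperfect"
                          else REASON_MULTI_HIT)
            elif rset.status == STATUS_REMOVED:
                reason = REASON_SET_REMOVED
            else:
                reason = REASON_LOST
            if p.probe_id in shortcut_lost and cl.cls in (CLASS_UNSPECIFIC,
                                                          CLASS_UNALIGNED):
                reason = REASON_LOST
            discards.append({"probe_id": p.probe_id,
                             "probeset_id": p.probeset_id, "reason": reason})
    for pid, reason in probe_map.rejected:
        discards.append({"probe_id": pid, "probeset_id": "", "reason": REASON_INVALID})
    return rows, discards


def _probeset_rows(revised):
    rows = []
    for r in revised.values():
        row = {c: "" for c in pio.PROBESET_TABLE_COLUMNS}
        row.update(probeset_id=r.probeset_id, status=r.status,
                   n_initial=r.n_initial, n_retained=r.n_retained,
                   retention_fraction=round(r.retention_fraction, 6),
                   gene_symbol=r.gene_symbol or "",
                   symbol_source=r.symbol_source)
        if r.span is not None:
            row.update(chrom=r.span.chrom, strand=r.span.strand,
                       span_start=r.span.start, span_end=r.span.end)
        rows.append(row)
    return rows


def _summarize(probe_map, classifications, revised, policy) -> RunSummary:
    class_counts: dict[str, int] = {}
    snp_hist: dict[str, int] = {}
    for cl in classifications.values():
        class_counts[cl.cls] = class_counts.get(cl.cls, 0) + 1
        if cl.is_specific and cl.position.footprint is not None:
            k = str(cl.position.n_snps_in_footprint)
            snp_hist[k] = snp_hist.get(k, 0) + 1
    venn = {"+".join(k): v
            for k, v in venn_partition(classifications.values()).items()}
    status_counts: dict[str, int] = {}
    source_counts: dict[str, int] = {}
    n_retained = 0
    n_half = 0
    genes = set()
    for r in revised.values():
        status_counts[r.status] = status_counts.get(r.status, 0) + 1
        n_retained += r.n_retained
        if r.status != STATUS_REMOVED:
            source_counts[r.symbol_source] = source_counts.get(r.symbol_source, 0) + 1
            if r.retention_fraction >= policy.retention_threshold:
                n_half += 1
            if r.gene_symbol and r.span is not None:
                genes.add(r.gene_symbol)
    total = len(probe_map.probes)
    summary = RunSummary(
        total_probes=total,
        n_rejected_rows=len(probe_map.rejected),
        class_counts=class_counts,
        venn=venn,
        probeset_status_counts=status_counts,
        symbol_source_counts=source_counts,
        n_probesets_initial=len(probe_map.probesets),
        n_probes_retained=n_retained,
        fraction_probes_best_choice=(n_retained / total if total else 0.0),
        n_probesets_half_retained=n_half,
        n_unique_genes=len(genes),
        snps_per_probe_hist=snp_hist)
    summary.check()
    return summary


def render_report(summary: RunSummary, fmt: str = "text") -> str:
    """Human-readable or JSON rendering of a run summary.

    Both renderings carry identical numbers; consistency identities are
    re-checked at render time.
    """
    summary.check()
    d = summary.to_dict()
    if fmt == "json":
        return json.dumps(d, indent=2, sort_keys=True) + "\n"
    lines = ["probe and probe-set revision summary",
             "=" * 38,
             f"probes (valid):                {d['total_probes']}",
             f"rejected probe-map rows:       {d['n_rejected_rows']}"]
    lines.append("probe classes:")
    for k, v in d["class_counts"].items():
        lines.append(f"  {k:<26} {v}")
    lines.append("perfect-hit database partition:")
    for k, v in d["venn"].items():
        lines.append(f"  {k:<26} {v}")
    lines.append("probe-set statuses:")
    for k, v in d["probeset_status_counts"].items():
        lines.append(f"  {k:<26} {v}")
    lines.append("annotation sources (retained sets):")
    for k, v in d["symbol_source_counts"].items():
        lines.append(f"  {k:<26} {v}")
    lines.append(f"probes in best-choice sets:    {d['n_probes_retained']} "
                 f"({100 * d['fraction_probes_best_choice']:.1f}%)")
    lines.append(f"probe sets >= retention thr.:  {d['n_probesets_half_retained']}")
    lines.append(f"unique annotated+positioned genes: {d['n_unique_genes']}")
    lines.append("SNPs per retained probe footprint:")
    for k, v in sorted(d["snps_per_probe_hist"].items(), key=lambda kv: int(kv[0])):
        lines.append(f"  {k:>3} SNPs {v}")
    return "\n".join(lines) + "\n"
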