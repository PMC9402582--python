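"""Seeded synthetic test platforms with planted ground truth.

The generator emits everything a run needs — a small multi-chromosome
genome (plus unplaced scaffolds), two transcript databases with shared
gene models and exon structure, an annotated sequence collection, known
SNVs, and a probe map — together with truth tables stating the expected
per-probe classification and per-probe-set outcome, constructed by
design rather than by running the pipeline:

* ``clean`` / ``junction`` probes copy exact (junction-spanning)
  transcript substrings -> transcript-specific.
* ``snp`` probes differ from their transcript at exactly one position
  where a variant with the matching alternate allele is planted ->
  transcript-specific after SNP forgiveness.
* ``multi`` probes are transcript substrings copied into a decoy
  transcript on a different chromosome -> two known-chromosome
  positions -> unspecific.
* ``dna`` probes copy intergenic genomic windows (alternating forward /
  reverse complement) -> genome-specific at rank 2.
* ``nt`` probes copy substrings of collection-only accessions ->
  genome-specific at rank 2 via the collection.
* ``unmappable`` probes are random sequences verified absent from every
  reference -> unaligned.

Probes of probe sets whose rank-1 fates already reach the retention
threshold are not carried into rank-2 mapping, so the truth tables mark
their ``dna``/``nt`` probes as unaligned rather than genome-specific.

Identical (spec, seed) pairs produce byte-identical files.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_fasta, write_gff3, write_probe_map, write_vcf
from .models import ProbeRecord, SNPRecord, TranscriptModel, revcomp

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "mutate_fixture",
           "FATES"]

FATE_CLEAN = "clean"
FATE_SNP = "snp"
FATE_JUNCTION = "junction"
FATE_MULTI = "multi"
FATE_DNA = "dna"
FATE_NT = "nt"
FATE_UNMAPPABLE = "unmappable"
FATES = (FATE_CLEAN, FATE_SNP, FATE_JUNCTION, FATE_MULTI, FATE_DNA, FATE_NT,
         FATE_UNMAPPABLE)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_fractions() -> dict[str, float]:
    return {FATE_CLEAN: 0.45, FATE_SNP: 0.15, FATE_JUNCTION: 0.10,
            FATE_MULTI: 0.08, FATE_DNA: 0.10, FATE_NT: 0.07,
            FATE_UNMAPPABLE: 0.05}


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic platform.

    Defaults emulate a compact gene-expression array slice: ~200 probe
    sets of 15-27 25-mers each, genes of 2-3 exons on three assembled
    chromosomes plus two unplaced scaffolds, with the probe fates mixed
    so that every branch of the workflow is exercised.
    """

    seed: int = 1
    n_chromosomes: int = 3
    chromosome_length: int = 140_000
    n_scaffolds: int = 2
    scaffold_length: int = 8_000
    n_probesets: int = 200
    probes_per_set: tuple[int, int] = (15, 27)
    exons_per_transcript: tuple[int, int] = (2, 3)
    exon_length: tuple[int, int] = (120, 250)
    intron_length: tuple[int, int] = (80, 300)
    variant_fraction: float = 0.3   # genes carrying a second transcript variant
    noise_snps_per_gene: float = 1.0
    fate_fractions: dict[str, float] = field(default_factory=_default_fractions)
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {"mixed": 0.70, "pure_rank1": 0.12,
                                 "rank2_dominant": 0.10, "dead": 0.08})
    probe_length: int = 25
    retention_threshold: float = 0.5
    include_planted_snps: bool = True

    def __post_init__(self) -> None:
        total = sum(self.fate_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fate fractions must sum to 1, got {total}")
        unknown = set(self.fate_fractions) - set(FATES)
        if unknown:
            raise ValueError(f"unknown fates {sorted(unknown)}")
        atotal = sum(self.archetype_fractions.values())
        if abs(atotal - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {atotal}")
        if self.probe_length > self.exon_length[0]:
            raise ValueError("probe length exceeds the shortest exon")


@dataclass
class Fixture:
    directory: Path
    config_path: Path
    probe_truth: list[dict]     # probe_id, probeset_id, fate, expected_class
    probeset_truth: list[dict]  # probeset_id, expected_status, ...
    paths: dict[str, Path]


class _Layout:
    """Per-chromosome cursor allocator for gene loci and spare windows."""

    def __init__(self, chrom_names, chrom_len, dup_len):
        self.chrom_len = chrom_len
        self.cursor = {c: 200 + dup_len + 100 for c in chrom_names}
        self.dup_start = {c: 200 for c in chrom_names}
        self.dup_cursor = {c: 200 for c in chrom_names}
        self.dup_end = {c: 200 + dup_len for c in chrom_names}

    def place(self, chrom, length):
        start = self.cursor[chrom]
        end = start + length
        if end > self.chrom_len - 10:
            raise ValueError(
                f"fixture does not fit: {chrom} needs {end} bases but has "
                f"{self.chrom_len}; reduce probe sets or enlarge chromosomes")
        self.cursor[chrom] = end + 50
        return start

    def dup_slot(self, chrom, length):
        start = self.dup_cursor[chrom]
        if start + length > self.dup_end[chrom]:
            raise ValueError(f"decoy pool exhausted on {chrom}")
        self.dup_cursor[chrom] = start + length
        return start


def _extract_transcript(genome, model: TranscriptModel) -> str:
    parts = []
    for s, e in model.exons:  # transcription order
        seg = genome[model.chrom][s:e].tobytes().decode()
        parts.append(revcomp(seg) if model.strand == "-" else seg)
    return "".join(parts)


def _tpos_to_genomic(model: TranscriptModel, tpos: int) -> int:
    off = 0
    for s, e in model.exons:
        if tpos < off + (e - s):
            return s + (tpos - off) if model.strand == "+" else e - 1 - (tpos - off)
        off += e - s
    raise ValueError("position outside transcript")


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Write a complete synthetic platform and its truth tables."""
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = spec.probe_length
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    scaffolds = [f"scaffold_{i + 1}" for i in range(spec.n_scaffolds)]
    genome: dict[str, np.ndarray] = {}
    for c in chroms:
        genome[c] = _BASES[rng.integers(0, 4, spec.chromosome_length)].copy()
    for s in scaffolds:
        genome[s] = _BASES[rng.integers(0, 4, spec.scaffold_length)].copy()
    dup_len = 8_000
    layout = _Layout(chroms, spec.chromosome_length, dup_len)

    # decoy transcripts: single-exon recipients of multi-hit copies
    models: dict[str, TranscriptModel] = {}
    dup_tx: dict[str, str] = {}
    for c in chroms:
        tx = f"DUPT_{c}"
        models[tx] = TranscriptModel(tx, c, "+",
                                     [(layout.dup_start[c], layout.dup_end[c])],
                                     gene_symbol=f"DUPGENE_{c}")
        dup_tx[c] = tx

    # --- plan probe sets -------------------------------------------------
    fates_order = list(FATES)
    # per-archetype fate distributions: 'mixed' follows the configured
    # fractions; the others skew a probe set toward one outcome so that
    # every probe-set status arises in a default fixture
    base = {f: spec.fate_fractions.get(f, 0.0) for f in fates_order}
    rank1_only = _renorm({f: base[f] for f in
                          (FATE_CLEAN, FATE_SNP, FATE_JUNCTION)})
    rank2_heavy = _renorm({FATE_DNA: 0.40, FATE_NT: 0.25, FATE_CLEAN: 0.10,
                           FATE_MULTI: 0.15, FATE_UNMAPPABLE: 0.10})
    dead_only = _renorm({FATE_MULTI: 0.5, FATE_UNMAPPABLE: 0.5})
    arch_dists = {"mixed": base, "pure_rank1": rank1_only,
                  "rank2_dominant": rank2_heavy, "dead": dead_only}
    arch_names = sorted(spec.archetype_fractions)
    arch_probs = np.array([spec.archetype_fractions[a] for a in arch_names])
    window_len = 30 * (spec.probes_per_set[1] + 1)
    plans = []
    for i in range(spec.n_probesets):
        chrom = chroms[i % len(chroms)]
        n_exons = int(rng.integers(spec.exons_per_transcript[0],
                                   spec.exons_per_transcript[1] + 1))
        exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1,
                                 n_exons)
        intron_lens = rng.integers(spec.intron_length[0],
                                   spec.intron_length[1] + 1,
                                   max(n_exons - 1, 0))
        locus_len = int(exon_lens.sum() + intron_lens.sum())
        locus_start = layout.place(chrom, locus_len + 50 + window_len)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = locus_start
        exons_fwd = []
        for j, el in enumerate(exon_lens):
            exons_fwd.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        exons = exons_fwd if strand == "+" else exons_fwd[::-1]
        window_start = locus_start + locus_len + 50
        n_probes = int(rng.integers(spec.probes_per_set[0],
                                    spec.probes_per_set[1] + 1))
        arch = arch_names[int(rng.choice(len(arch_names), p=arch_probs))]
        dist = arch_dists[arch]
        probs = np.array([dist.get(f, 0.0) for f in fates_order])
        fates = [fates_order[k] for k in rng.choice(len(fates_order),
                                                    size=n_probes, p=probs)]
        plans.append(dict(i=i, chrom=chrom, strand=strand, exons=exons,
                          window_start=window_start, fates=fates))

    # gene models and transcript databases (shared between the two rank-1
    # databases; a fraction of genes gains a variant lacking the 5' exon)
    for plan in plans:
        i = plan["i"]
        sym = f"GENE{i:04d}"
        for acc in (f"REF_{i:04d}", f"ENS_{i:04d}"):
            models[acc] = TranscriptModel(acc, plan["chrom"], plan["strand"],
                                          list(plan["exons"]), sym)
        plan["variant"] = (len(plan["exons"]) > 1
                           and rng.random() < spec.variant_fraction)
        if plan["variant"]:
            for acc in (f"REF_{i:04d}V2", f"ENS_{i:04d}V2"):
                models[acc] = TranscriptModel(acc, plan["chrom"], plan["strand"],
                                              list(plan["exons"][1:]), sym)

    # --- phase 1: choose rank-1 probe positions, apply multi-hit copies --
    for plan in plans:
        model = models[f"REF_{plan['i']:04d}"]
        tlen = model.length
        spans, off = [], 0
        for s, e in model.exons:
            spans.append((off, off + (e - s)))
            off += e - s
        donors: list[int] = []      # one entry per multi-fate probe
        distinct: list[int] = []    # unique donor windows actually copied
        for fate in plan["fates"]:
            if fate != FATE_MULTI:
                continue
            placed = False
            for _ in range(200):
                ts, te = spans[int(rng.integers(0, len(spans)))]
                if te - ts < L:
                    continue
                p = int(rng.integers(ts, te - L + 1))
                if all(abs(p - q) >= L for q in distinct):
                    distinct.append(p)
                    donors.append(p)
                    placed = True
                    break
            if not placed:
                # window space exhausted: share an existing donor (the
                # probes then carry identical sequences, which is legal)
                if not distinct:
                    raise ValueError("could not place a multi-hit donor window")
                donors.append(distinct[len(donors) % len(distinct)])
        plan["donor_positions"] = donors
        plan["donor_distinct"] = distinct
        positions = []
        for fate in plan["fates"]:
            if fate == FATE_JUNCTION and len(spans) > 1:
                j = int(rng.integers(1, len(spans)))
                boundary = spans[j][0]
                lo = max(boundary - (L - 3), 0)
                hi = min(boundary - 3, tlen - L)
                p = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
            elif fate in (FATE_CLEAN, FATE_SNP, FATE_JUNCTION):
                p = int(rng.integers(0, tlen - L + 1))
            else:
                positions.append(None)
                continue
            for _ in range(200):
                if all(abs(p - d) >= L for d in distinct):
                    break
                p = int(rng.integers(0, tlen - L + 1))
            else:
                raise ValueError("could not separate a probe from donor windows")
            positions.append(p)
        plan["positions"] = positions
        # copy donor content into a decoy transcript on another chromosome
        recipients = [c for c in (chroms * 2) if c != plan["chrom"]]
        for k, p in enumerate(distinct):
            seq_t = _transcript_substring(genome, model, p, L)
            dest_chrom = recipients[k % len(recipients)]
            dest = layout.dup_slot(dest_chrom, L)
            genome[dest_chrom][dest:dest + L] = np.frombuffer(
                seq_t.encode(), dtype=np.uint8)

    # --- phase 2: finalize genome, extract transcripts, emit probes ------
    genome_str = {c: a.tobytes().decode() for c, a in genome.items()}
    tx_seqs = {acc: _extract_transcript(genome, m) for acc, m in models.items()}

    probes: list[ProbeRecord] = []
    probe_truth: list[dict] = []
    probeset_truth: list[dict] = []
    snp_records: list[SNPRecord] = []
    planted_snps: list[SNPRecord] = []
    nt_seqs: dict[str, str] = {}
    nt_symbols: dict[str, str] = {}
    all_ref_text_parts = [*genome_str.values(), *tx_seqs.values()]

    for plan in plans:
        i = plan["i"]
        psid = f"PS{i:04d}"
        model = models[f"REF_{i:04d}"]
        tseq = tx_seqs[f"REF_{i:04d}"]
        fates = plan["fates"]
        n = len(fates)
        a = sum(1 for f in fates if f in (FATE_CLEAN, FATE_SNP, FATE_JUNCTION))
        shortcut = a > 0 and a / n >= spec.retention_threshold
        donors = list(plan["donor_positions"])
        dna_slot = 0
        nt_acc = None
        if any(f == FATE_NT for f in fates):
            nt_acc = f"NT_{i:04d}"
            nt_seqs[nt_acc] = "".join(
                "ACGT"[b] for b in rng.integers(0, 4, 300))
            nt_symbols[nt_acc] = f"NTSYM{i:04d}"
            all_ref_text_parts.append(nt_seqs[nt_acc])
        for j, fate in enumerate(fates):
            pid = f"P{i:04d}_{j:02d}"
            p = plan["positions"][j]
            if fate in (FATE_CLEAN, FATE_JUNCTION):
                seq = tseq[p:p + L]
                expected = "rank1_specific"
            elif fate == FATE_SNP:
                o = int(rng.integers(2, L - 2))
                orig = tseq[p + o]
                alt = "ACGT"[("ACGT".index(orig) + 1 + int(rng.integers(0, 3))) % 4]
                seq = tseq[p:p + o] + alt + tseq[p + o + 1:p + L]
                gpos = _tpos_to_genomic(model, p + o)
                plus_alt = alt if model.strand == "+" else revcomp(alt)
                ref_base = genome_str[model.chrom][gpos]
                rec = SNPRecord(model.chrom, gpos, ref_base,
                                frozenset({plus_alt}))
                planted_snps.append(rec)
                if spec.include_planted_snps:
                    snp_records.append(rec)
                expected = "rank1_specific"
            elif fate == FATE_MULTI:
                p = donors.pop(0)
                seq = tseq[p:p + L]
                expected = "unspecific"
            elif fate == FATE_DNA:
                start = plan["window_start"] + dna_slot * 30
                dna_slot += 1
                gseq = genome_str[plan["chrom"]][start:start + L]
                # whole-set orientation: region clustering is strand-aware
                seq = gseq if i % 2 == 0 else revcomp(gseq)
                expected = "unaligned" if shortcut else "rank2_specific"
            elif fate == FATE_NT:
                off = int(rng.integers(0, 300 - L + 1))
                seq = nt_seqs[nt_acc][off:off + L]
                expected = "unaligned" if shortcut else "rank2_specific"
            else:  # unmappable
                seq = _unmappable_seq(rng, L, all_ref_text_parts)
                expected = "unaligned"
            probes.append(ProbeRecord(pid, psid, seq))
            probe_truth.append(dict(probe_id=pid, probeset_id=psid, fate=fate,
                                    expected_class=expected))
        probeset_truth.append(_expected_probeset(
            psid, fates, spec.retention_threshold, f"GENE{i:04d}",
            nt_symbols.get(nt_acc) if nt_acc else None))
        # background variation: harmless SNVs inside exons
        for _ in range(rng.poisson(spec.noise_snps_per_gene)):
            ts, te = model.exons[int(rng.integers(0, len(model.exons)))]
            gpos = int(rng.integers(ts, te))
            if any(r.pos == gpos and r.chrom == model.chrom
                   for r in planted_snps):
                continue
            ref_base = genome_str[model.chrom][gpos]
            alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
            snp_records.append(SNPRecord(model.chrom, gpos, ref_base,
                                         frozenset({alt})))

    _verify_plants(probes, probe_truth, tx_seqs, genome_str, nt_seqs,
                   planted_snps, plans, models, spec)

    # --- write files ------------------------------------------------------
    paths = {
        "genome": out_dir / "genome.fa",
        "refseq": out_dir / "refseq.fa",
        "ensembl": out_dir / "ensembl.fa",
        "nt": out_dir / "nt.fa",
        "gene_model": out_dir / "genes.gff3",
        "variants": out_dir / "snps.vcf",
        "probe_map": out_dir / "probes.tsv",
        "config": out_dir / "config.yaml",
        "probe_truth": out_dir / "probes_truth.tsv",
        "probeset_truth": out_dir / "probesets_truth.tsv",
        "planted_snps": out_dir / "planted_snps.vcf",
    }
    write_fasta(paths["genome"], genome_str)
    ref_accs = sorted(a for a in tx_seqs if a.startswith(("REF_", "DUPT_")))
    ens_accs = sorted(a for a in tx_seqs if a.startswith(("ENS_", "DUPT_")))
    write_fasta(paths["refseq"], {a: tx_seqs[a] for a in ref_accs})
    write_fasta(paths["ensembl"], {a: tx_seqs[a] for a in ens_accs})
    write_fasta(paths["nt"], nt_seqs, nt_symbols)
    write_gff3(paths["gene_model"], [models[a] for a in sorted(models)])
    contigs = {c: len(genome_str[c]) for c in genome_str}
    write_vcf(paths["variants"], _merge_snps(snp_records), contigs)
    write_vcf(paths["planted_snps"], _merge_snps(planted_snps), contigs)
    write_probe_map(paths["probe_map"], probes)
    _write_truth(paths["probe_truth"], probe_truth,
                 ["probe_id", "probeset_id", "fate", "expected_class"])
    _write_truth(paths["probeset_truth"], probeset_truth,
                 ["probeset_id", "expected_status", "expected_symbol",
                  "expected_symbol_source", "n_initial"])
    _write_config(paths["config"], chroms, spec)
    return Fixture(out_dir, paths["config"], probe_truth, probeset_truth, paths)


def _renorm(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _transcript_substring(genome, model: TranscriptModel, tpos: int, L: int) -> str:
    off = 0
    for s, e in model.exons:
        if tpos < off + (e - s):
            if model.strand == "+":
                g0 = s + (tpos - off)
                return genome[model.chrom][g0:g0 + L].tobytes().decode()
            g1 = e - (tpos - off)
            return revcomp(genome[model.chrom][g1 - L:g1].tobytes().decode())
        off += e - s
    raise ValueError("donor position outside transcript")


def _unmappable_seq(rng, L, reference_texts, max_tries: int = 100) -> str:
    for _ in range(max_tries):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, L))
        rc = revcomp(seq)
        if not any(seq in t or rc in t for t in reference_texts):
            return seq
    raise ValueError("could not draw an unmappable probe sequence")


def _expected_probeset(psid, fates, threshold, gene_symbol, nt_symbol):
    n = len(fates)
    a = sum(1 for f in fates if f in (FATE_CLEAN, FATE_SNP, FATE_JUNCTION))
    dna_ct = sum(1 for f in fates if f == FATE_DNA)
    nt_ct = sum(1 for f in fates if f == FATE_NT)
    row = dict(probeset_id=psid, n_initial=n)
    if a == n:
        row.update(expected_status="unchanged", expected_symbol=gene_symbol,
                   expected_symbol_source="refseq_and_ensembl")
        return row
    if a > 0 and a / n >= threshold:
        row.update(expected_status="revised_rank1", expected_symbol=gene_symbol,
                   expected_symbol_source="refseq_and_ensembl")
        return row
    b = max(dna_ct, nt_ct)
    if a == 0 and b == 0:
        row.update(expected_status="removed", expected_symbol="",
                   expected_symbol_source="none")
        return row
    if a >= b:  # dominance; ties prefer the annotated rank-1 candidate
        row.update(expected_status="revised_rank1", expected_symbol=gene_symbol,
                   expected_symbol_source="refseq_and_ensembl")
        return row
    if nt_ct >= dna_ct:  # collection groups win ties within candidate B
        row.update(expected_status="rank2", expected_symbol=nt_symbol or "",
                   expected_symbol_source="nt")
    else:
        row.update(expected_status="rank2", expected_symbol="",
                   expected_symbol_source="dna_region")
    return row


def _verify_plants(probes, probe_truth, tx_seqs, genome_str, nt_seqs,
                   planted_snps, plans, models, spec) -> None:
    """Check every plant by direct string comparison against the outputs."""
    L = spec.probe_length
    by_id = {p.probe_id: p for p in probes}
    planted_sites = {(r.chrom, r.pos): r for r in planted_snps}
    for row, plan in zip(probe_truth, _rows_to_plans(probe_truth, plans)):
        p = by_id[row["probe_id"]]
        fate = row["fate"]
        i = plan["i"]
        tseq = tx_seqs[f"REF_{i:04d}"]
        if fate in (FATE_CLEAN, FATE_JUNCTION, FATE_MULTI):
            assert p.sequence in tseq, f"{p.probe_id}: plant not in transcript"
        if fate == FATE_SNP:
            j = int(row["probe_id"].rsplit("_", 1)[1])
            tp = plan["positions"][j]
            window = tseq[tp:tp + L]
            diff = [k for k in range(L) if window[k] != p.sequence[k]]
            assert len(diff) == 1, f"{p.probe_id}: expected exactly one mismatch"
            model = models[f"REF_{i:04d}"]
            gpos = _tpos_to_genomic(model, tp + diff[0])
            rec = planted_sites.get((model.chrom, gpos))
            assert rec is not None, f"{p.probe_id}: planted SNV missing"
        if fate == FATE_MULTI:
            n_tx = sum(tx_seqs[acc].count(p.sequence)
                       for acc in tx_seqs if acc.startswith(("REF_", "DUPT_")))
            assert n_tx >= 2, f"{p.probe_id}: duplicate copy missing"
        if fate == FATE_DNA:
            g = genome_str[plan["chrom"]]
            assert p.sequence in g or revcomp(p.sequence) in g
        if fate == FATE_NT:
            assert any(p.sequence in s for s in nt_seqs.values())
        if fate == FATE_UNMAPPABLE:
            rc = revcomp(p.sequence)
            assert not any(p.sequence in t or rc in t
                           for t in (*genome_str.values(), *tx_seqs.values(),
                                     *nt_seqs.values()))


def _rows_to_plans(probe_truth, plans):
    by_ps = {f"PS{p['i']:04d}": p for p in plans}
    return [by_ps[row["probeset_id"]] for row in probe_truth]


def _merge_snps(records):
    merged: dict[tuple[str, int], SNPRecord] = {}
    for r in records:
        key = (r.chrom, r.pos)
        prev = merged.get(key)
        if prev is None:
            merged[key] = r
        else:
            merged[key] = SNPRecord(r.chrom, r.pos, prev.ref_allele,
                                    prev.alt_alleles | r.alt_alleles)
    return list(merged.values())


def _write_truth(path, rows, columns):
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def _write_config(path, chroms, spec: FixtureSpec) -> None:
    import yaml

    cfg = {
        "probe_map": "probes.tsv",
        "gene_model": "genes.gff3",
        "variants": "snps.vcf",
        "probe_length": spec.probe_length,
        "retention_threshold": spec.retention_threshold,
        "known_chromosomes": chroms,
        "databases": [
            {"name": "refseq", "path": "refseq.fa", "rank": 1,
             "type": "transcript"},
            {"name": "ensembl", "path": "ensembl.fa", "rank": 1,
             "type": "transcript"},
            {"name": "nt", "path": "nt.fa", "rank": 2, "type": "collection"},
            {"name": "dna", "path": "genome.fa", "rank": 2, "type": "genomic"},
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_truth(directory: str | Path) -> tuple[list[dict], list[dict]]:
    """Read the truth tables back from a generated fixture directory."""
    directory = Path(directory)

    def read(path):
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            return [dict(zip(header, line.rstrip("\n").split("\t")))
                    for line in fh]

    return (read(directory / "probes_truth.tsv"),
            read(directory / "probesets_truth.tsv"))


def mutate_fixture(fixture_dir: str | Path, perturbation: str,
                   dest_dir: str | Path, seed: int = 0) -> Path:
    """Controlled fixture perturbations for property tests.

    ``drop_db``: remove all rank-2 databases from the configuration.
    ``add_snps``: append the planted mismatch SNVs to the variant file.
    ``shuffle_rows``: shuffle the probe-map rows (header kept).
    """
    src, dest = Path(fixture_dir), Path(dest_dir)
    if dest.exists():
        shutil.rmtree(dest)
    shutil.copytree(src, dest, ignore=shutil.ignore_patterns("*.fai"))
    if perturbation == "drop_db":
        import yaml
        cfg_path = dest / "config.yaml"
        with open(cfg_path) as fh:
            cfg = yaml.safe_load(fh)
        min_rank = min(d["rank"] for d in cfg["databases"])
        cfg["databases"] = [d for d in cfg["databases"]
                            if d["rank"] == min_rank]
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
    elif perturbation == "add_snps":
        existing = (dest / "snps.vcf").read_text().splitlines()
        planted = [ln for ln in (dest / "planted_snps.vcf").read_text().splitlines()
                   if not ln.startswith("#")]
        seen = {tuple(ln.split("\t")[:2]) for ln in existing
                if not ln.startswith("#")}
        new = [ln for ln in planted if tuple(ln.split("\t")[:2]) not in seen]
        body = [ln for ln in existing if not ln.startswith("#")] + new
        header = [ln for ln in existing if ln.startswith("#")]
        body.sort(key=lambda ln: (ln.split("\t")[0], int(ln.split("\t")[1])))
        (dest / "snps.vcf").write_text("\n".join(header + body) + "\n")
    elif perturbation == "shuffle_rows":
        rng = np.random.default_rng(seed)
        lines = (dest / "probes.tsv").read_text().splitlines()
        header, rows = lines[0], lines[1:]
        order = rng.permutation(len(rows))
        (dest / "probes.tsv").write_text(
            "\n".join([header] + [rows[k] for k in order]) + "\n")
    else:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    return dest
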