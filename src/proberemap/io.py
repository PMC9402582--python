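"""Input parsing, validation and table output.

Every reader converts from the file format's native coordinate
convention (GFF/GTF and VCF are 1-based) to the package-internal
0-based half-open convention exactly once; the writers in this module
emit plain TSV and the standard text formats (FASTA, GFF3, GTF, VCF)
used by the synthetic fixture generator.
"""

from __future__ import annotations

import csv
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from cyvcf2 import VCF
from pyfaidx import Fasta

from .models import (DB_TYPES, DEFAULT_POLICIES, VALID_BASES, AlignmentPolicy,
                     AssemblyPolicy, GeneModel, ProbeRecord, ProbeSetRecord,
                     ReferenceDB, SNPRecord, TranscriptModel)
from .projection import SnpIndex


class ConfigError(Exception):
    """Fatal problem with the run configuration or a required input."""


# ---------------------------------------------------------------------------
# probe map
# ---------------------------------------------------------------------------

@dataclass
class ProbeMapResult:
    probes: list[ProbeRecord]
    probesets: list[ProbeSetRecord]
    rejected: list[tuple[str, str]]  # (probe_id or line repr, reason)


def read_probe_map(path: str | Path, probe_length: int = 25) -> ProbeMapResult:
    """Read the probe map TSV (columns probe_id, probeset_id, sequence).

    Rows with a wrong-length or non-ACGT sequence are rejected and
    counted; a duplicate probe_id or a missing column is fatal.  Probe
    sets preserve the row order of their probes.
    """
    path = Path(path)
    probes: list[ProbeRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    sets: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"probe_id", "probeset_id", "sequence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(
                f"{path}: probe map must have columns {sorted(required)}")
        for row in reader:
            pid = (row["probe_id"] or "").strip()
            psid = (row["probeset_id"] or "").strip()
            seq = (row["sequence"] or "").strip().upper()
            if not pid or not psid:
                rejected.append((pid or "<blank>", "missing_id"))
                continue
            if pid in seen:
                raise ConfigError(f"{path}: duplicate probe_id {pid!r}")
            seen.add(pid)
            if len(seq) != probe_length:
                rejected.append((pid, "wrong_length"))
                continue
            if not set(seq) <= VALID_BASES:
                rejected.append((pid, "invalid_characters"))
                continue
            probes.append(ProbeRecord(pid, psid, seq))
            sets.setdefault(psid, []).append(pid)
    if not probes and not rejected:
        import warnings
        warnings.warn(f"{path}: probe map contains no data rows")
    probesets = [ProbeSetRecord(psid, pids) for psid, pids in sets.items()]
    return ProbeMapResult(probes, probesets, rejected)


def write_probe_map(path: str | Path, probes: Iterable[ProbeRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tprobeset_id\tsequence\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.probeset_id}\t{p.sequence}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a FASTA into (accession -> sequence, accession -> gene symbol).

    A ``gene=SYMBOL`` token in the header description attaches a symbol
    to the accession (used by annotated sequence collections).
    """
    fa = Fasta(str(path), read_long_names=True, rebuild=True)
    sequences: dict[str, str] = {}
    symbols: dict[str, str] = {}
    for long_name in fa.keys():
        parts = long_name.split()
        acc = parts[0]
        if acc in sequences:
            raise ConfigError(f"{path}: duplicate accession {acc!r}")
        sequences[acc] = str(fa[long_name][:]).upper()
        for token in parts[1:]:
            if token.startswith("gene="):
                symbols[acc] = token[5:]
    return sequences, symbols


def write_fasta(path: str | Path, sequences: dict[str, str],
                symbols: Optional[dict[str, str]] = None, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc in sequences:
            desc = f" gene={symbols[acc]}" if symbols and acc in symbols else ""
            fh.write(f">{acc}{desc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gene model (GFF3 / GTF)
# ---------------------------------------------------------------------------

def _gene_symbol_from_attrs(attrs) -> Optional[str]:
    for key in ("gene_name", "gene"):
        if key in attrs:
            val = attrs[key]
            return val[0] if isinstance(val, list) else val
    return None


def read_gene_model(path: str | Path) -> GeneModel:
    """Assemble per-transcript exon chains from a GFF3 or GTF file.

    Exon chains are sorted 5'->3' in transcription order (descending
    genomic coordinate on the minus strand).  Transcripts with
    overlapping exons are dropped with a count; lines that are not
    9-field GFF records are skipped with a count.
    """
    import gffutils

    path = Path(path)
    n_skipped = 0
    clean_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if line.rstrip("\n").count("\t") != 8:
                n_skipped += 1
                continue
            clean_lines.append(line)
    with tempfile.NamedTemporaryFile("w", suffix=path.suffix, delete=False) as tmp:
        tmp.writelines(clean_lines)
        tmp_path = tmp.name
    try:
        db = gffutils.create_db(
            tmp_path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True)
    finally:
        os.unlink(tmp_path)

    per_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, Optional[str]]] = {}
    parent_symbol_cache: dict[str, Optional[str]] = {}
    for exon in db.features_of_type("exon"):
        attrs = exon.attributes
        if "transcript_id" in attrs:
            tx_id = attrs["transcript_id"][0]
        elif "Parent" in attrs:
            tx_id = attrs["Parent"][0]
        else:
            n_skipped += 1
            continue
        symbol = _gene_symbol_from_attrs(attrs)
        if symbol is None:
            if tx_id not in parent_symbol_cache:
                sym = None
                try:
                    sym = _gene_symbol_from_attrs(db[tx_id].attributes)
                except Exception:
                    sym = None
                parent_symbol_cache[tx_id] = sym
            symbol = parent_symbol_cache[tx_id]
        per_tx.setdefault(tx_id, []).append((exon.start - 1, exon.end))
        tx_meta.setdefault(tx_id, (exon.seqid, exon.strand, symbol))

    transcripts: dict[str, TranscriptModel] = {}
    n_dropped = 0
    for tx_id, exons in per_tx.items():
        chrom, strand, symbol = tx_meta[tx_id]
        exons = sorted(exons)
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            n_dropped += 1
            continue
        if strand == "-":
            exons = exons[::-1]
        transcripts[tx_id] = TranscriptModel(tx_id, chrom, strand, exons, symbol)
    return GeneModel(transcripts, n_skipped_lines=n_skipped,
                     n_dropped_transcripts=n_dropped)


def write_gff3(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    """Write a minimal GFF3 gene model (mRNA + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tm in transcripts:
            exons = sorted(tm.exons)
            start, end = exons[0][0] + 1, exons[-1][1]
            sym = f";gene_name={tm.gene_symbol}" if tm.gene_symbol else ""
            fh.write(f"{tm.chrom}\tproberemap\tmRNA\t{start}\t{end}\t.\t"
                     f"{tm.strand}\t.\tID={tm.transcript_id}{sym}\n")
            for s, e in exons:
                fh.write(f"{tm.chrom}\tproberemap\texon\t{s + 1}\t{e}\t.\t"
                         f"{tm.strand}\t.\tParent={tm.transcript_id}\n")


def write_gtf(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    """Write the same gene model in GTF dialect."""
    with open(path, "w") as fh:
        for tm in transcripts:
            for s, e in sorted(tm.exons):
                attrs = f'gene_id "{tm.transcript_id}_g"; transcript_id "{tm.transcript_id}";'
                if tm.gene_symbol:
                    attrs += f' gene_name "{tm.gene_symbol}";'
                fh.write(f"{tm.chrom}\tproberemap\texon\t{s + 1}\t{e}\t.\t"
                         f"{tm.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# variants (VCF)
# ---------------------------------------------------------------------------

@dataclass
class SnvReadResult:
    index: SnpIndex
    n_loaded: int
    n_skipped: int  # indels / multi-base / symbolic records


def read_snvs(path: str | Path) -> SnvReadResult:
    """Load SNVs from a VCF; indels and multi-base records are skipped.

    VCF 1-based positions become internal 0-based coordinates.
    """
    records: list[SNPRecord] = []
    n_skipped = 0
    bases = VALID_BASES
    for var in VCF(str(path)):
        alts = [a for a in (var.ALT or [])]
        if (len(var.REF) != 1 or var.REF not in bases or not alts
                or any(len(a) != 1 or a not in bases for a in alts)):
            n_skipped += 1
            continue
        records.append(SNPRecord(var.CHROM, var.POS - 1, var.REF,
                                 frozenset(alts)))
    return SnvReadResult(SnpIndex(records), len(records), n_skipped)


def write_vcf(path: str | Path, records: Iterable[SNPRecord],
              contigs: Optional[dict[str, int]] = None) -> None:
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            alts = ",".join(sorted(r.alt_alleles))
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref_allele}\t{alts}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class DBConfig:
    name: str
    path: str
    rank: int
    db_type: str
    max_mismatches: Optional[int] = None
    allow_reverse_complement: Optional[bool] = None
    min_length: Optional[int] = None  # optional length filter (collections)
    max_length: Optional[int] = None

    def policy(self) -> AlignmentPolicy:
        default = DEFAULT_POLICIES[self.db_type]
        return AlignmentPolicy(
            self.max_mismatches if self.max_mismatches is not None
            else default.max_mismatches,
            self.allow_reverse_complement if self.allow_reverse_complement is not None
            else default.allow_reverse_complement)


@dataclass
class RunConfig:
    probe_map: str
    databases: list[DBConfig]
    gene_model: Optional[str] = None
    variants: Optional[str] = None
    probe_length: int = 25
    retention_threshold: float = 0.5
    known_chromosomes: list[str] = field(default_factory=list)
    cluster_gap: int = 100_000
    allele_strict: bool = True
    strict_threshold: bool = False
    multi_hit_falls_through: bool = False

    def assembly_policy(self) -> AssemblyPolicy:
        return AssemblyPolicy(self.retention_threshold, "prefer_A",
                              self.strict_threshold, self.cluster_gap)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Relative paths are resolved against the config file's directory.
    Declaring a transcript or genomic database with a nonzero mismatch
    cap requires a variant file (SNP correction is impossible without
    one).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    base = path.parent

    def resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    dbs = []
    names = set()
    for entry in raw.get("databases", []):
        db_type = entry.get("type", entry.get("db_type"))
        if db_type not in DB_TYPES:
            raise ConfigError(f"database {entry.get('name')!r}: bad type {db_type!r}")
        name = entry["name"]
        if name in names:
            raise ConfigError(f"duplicate database name {name!r}")
        names.add(name)
        dbs.append(DBConfig(
            name=name, path=resolve(entry["path"]), rank=int(entry["rank"]),
            db_type=db_type,
            max_mismatches=entry.get("max_mismatches"),
            allow_reverse_complement=entry.get("allow_reverse_complement"),
            min_length=entry.get("min_length"),
            max_length=entry.get("max_length")))
    if not dbs:
        raise ConfigError("config declares no databases")
    cfg = RunConfig(
        probe_map=resolve(raw["probe_map"]),
        databases=dbs,
        gene_model=resolve(raw.get("gene_model")),
        variants=resolve(raw.get("variants")),
        probe_length=int(raw.get("probe_length", 25)),
        retention_threshold=float(raw.get("retention_threshold", 0.5)),
        known_chromosomes=list(raw.get("known_chromosomes", [])),
        cluster_gap=int(raw.get("cluster_gap", 100_000)),
        allele_strict=bool(raw.get("allele_strict", True)),
        strict_threshold=bool(raw.get("strict_threshold", False)),
        multi_hit_falls_through=bool(raw.get("multi_hit_falls_through", False)))
    needs_snps = any(d.policy().max_mismatches > 0 and d.db_type != "collection"
                     for d in dbs)
    if needs_snps and (cfg.variants is None or not Path(cfg.variants).exists()):
        raise ConfigError(
            "a transcript/genomic database allows mismatches but no variant "
            "file is available: SNP correction is impossible")
    if any(d.db_type == "transcript" for d in dbs) and cfg.gene_model is None:
        raise ConfigError("a transcript database requires a gene model")
    return cfg


def load_reference_db(dbc: DBConfig) -> ReferenceDB:
    sequences, symbols = read_fasta(dbc.path)
    if dbc.db_type == "collection" and (dbc.min_length or dbc.max_length):
        lo = dbc.min_length or 0
        hi = dbc.max_length or float("inf")
        sequences = {a: s for a, s in sequences.items() if lo <= len(s) <= hi}
        symbols = {a: s for a, s in symbols.items() if a in sequences}
    return ReferenceDB(dbc.name, dbc.rank, dbc.db_type, sequences,
                       dbc.policy(), symbols)


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

PROBE_TABLE_COLUMNS = [
    "probe_id", "probeset_id_initial", "probeset_id_revised", "class", "rank",
    "db_names", "chrom", "strand", "start", "end", "blocks",
    "raw_mismatches", "effective_mismatches", "n_snps_in_footprint",
]

PROBESET_TABLE_COLUMNS = [
    "probeset_id", "status", "n_initial", "n_retained", "retention_fraction",
    "gene_symbol", "symbol_source", "chrom", "strand", "span_start", "span_end",
]


def _write_table(rows: list[dict], columns: list[str], sort_by: list[str],
                 path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=columns)
    if len(df):
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_probe_table(rows: list[dict], path: str | Path) -> None:
    """Probe-level annotation table, canonically sorted by probe_id."""
    _write_table(rows, PROBE_TABLE_COLUMNS, ["probe_id"], path)


def write_probeset_table(rows: list[dict], path: str | Path) -> None:
    """Probe-set-level annotation table, canonically sorted by probeset_id."""
    _write_table(rows, PROBESET_TABLE_COLUMNS, ["probeset_id"], path)


def write_discard_log(rows: list[dict], path: str | Path) -> None:
    _write_table(rows, ["probe_id", "probeset_id", "reason"], ["probe_id"], path)
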