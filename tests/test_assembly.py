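"""Candidate A/B construction, retention threshold and dominance."""

import pytest

from proberemap.assembly import (assemble, build_candidate_A,
                                 build_candidate_B, resolve_symbol_source)
from proberemap.models import (AssemblyPolicy, Candidate, GenomicFootprint,
                               ProbeSetRecord)
from proberemap.ranking import aggregate_positions

from test_ranking import _ca

POLICY = AssemblyPolicy()


def _rank1_cls(symbol, chrom="chr1", start=100, dbs=("refseq", "ensembl")):
    from proberemap.models import ProbeClassification
    cas = [_ca(db, f"t_{db}", chrom=chrom, blocks=((start, start + 25),))
           for db in dbs]
    pos = aggregate_positions(cas, {(db, f"t_{db}"): symbol for db in dbs})[0]
    return ProbeClassification("x", "rank1_specific", rank=1, position=pos,
                               db_provenance=frozenset(dbs))


def _rank2_cls(kind, chrom="chr1", start=1000, acc="NT_1", symbol="NTSYM"):
    from proberemap.models import ProbeClassification
    if kind == "nt":
        cas = [_ca("nt", acc, pseudo=True, start=start)]
        pos = aggregate_positions(cas, {("nt", acc): symbol})[0]
    else:
        cas = [_ca("dna", chrom, chrom=chrom, blocks=((start, start + 25),))]
        pos = aggregate_positions(cas)[0]
    return ProbeClassification("x", "rank2_specific", rank=2, position=pos,
                               db_provenance=pos and frozenset(
                                   e[0] for e in pos.supporting))


def _other_cls():
    from proberemap.models import ProbeClassification
    return ProbeClassification("x", "unspecific", reason="multi_hit")


class TestCandidateA:
    def test_single_shared_symbol(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(20)])
        cls = {f"p{i}": (_rank1_cls("GENE1") if i < 15 else _other_cls())
               for i in range(20)}
        cand = build_candidate_A(ps, cls)
        assert cand.size == 15 and cand.gene_symbol == "GENE1"
        assert not cand.symbol_conflict

    def test_absent_without_rank1_probes(self):
        ps = ProbeSetRecord("s", ["p0", "p1"])
        cls = {"p0": _other_cls(), "p1": _other_cls()}
        assert build_candidate_A(ps, cls) is None

    def test_symbol_conflict_resolves_to_plurality(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(10)])
        cls = {f"p{i}": _rank1_cls("GENE1" if i < 6 else "GENE2",
                                   start=100 + 30 * i)
               for i in range(10)}
        cand = build_candidate_A(ps, cls)
        assert cand.size == 6 and cand.gene_symbol == "GENE1"
        assert cand.symbol_conflict

    def test_symbol_tie_breaks_lexicographically(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(4)])
        cls = {f"p{i}": _rank1_cls("GENEB" if i < 2 else "GENEA",
                                   start=100 + 30 * i)
               for i in range(4)}
        cand = build_candidate_A(ps, cls)
        assert cand.gene_symbol == "GENEA"

    def test_no_symbols_keeps_all_rank1_probes(self):
        ps = ProbeSetRecord("s", ["p0", "p1"])
        cls = {f"p{i}": _rank1_cls(None, start=100 + 30 * i) for i in range(2)}
        cand = build_candidate_A(ps, cls)
        assert cand.size == 2 and cand.gene_symbol is None


class TestCandidateB:
    def test_clustered_genomic_region(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(5)])
        cls = {f"p{i}": _rank2_cls("dna", start=1000 + 500 * i)
               for i in range(5)}
        cand = build_candidate_B(ps, cls, POLICY)
        assert cand.size == 5 and cand.group_label == "dna_region"
        assert cand.gene_symbol is None

    def test_far_apart_hits_split_into_clusters(self):
        ps = ProbeSetRecord("s", ["p0", "p1", "p2"])
        cls = {"p0": _rank2_cls("dna", start=1000),
               "p1": _rank2_cls("dna", start=1500),
               "p2": _rank2_cls("dna", start=1000 + 200_000)}
        cand = build_candidate_B(ps, cls, POLICY)
        assert cand.size == 2

    def test_larger_collection_group_dominates_dna(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(5)])
        cls = {f"p{i}": _rank2_cls("nt", start=10 * i) for i in range(3)}
        cls.update({f"p{i}": _rank2_cls("dna", start=5000 + 30 * i)
                    for i in range(3, 5)})
        cand = build_candidate_B(ps, cls, POLICY)
        assert cand.size == 3 and cand.group_label == "nt"
        assert cand.gene_symbol == "NTSYM"

    def test_equal_groups_prefer_collection_annotation(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(4)])
        cls = {f"p{i}": _rank2_cls("nt", start=10 * i) for i in range(2)}
        cls.update({f"p{i}": _rank2_cls("dna", start=5000 + 30 * i)
                    for i in range(2, 4)})
        cand = build_candidate_B(ps, cls, POLICY)
        assert cand.group_label == "nt"


def _candidate(kind, n, label=""):
    probes = [f"{kind}{i}" for i in range(n)]
    span = GenomicFootprint("chr1", "+", ((0, 25),), True) if n else None
    return Candidate(kind, probes, "SYM" if kind == "A" else None,
                     frozenset({"refseq"} if kind == "A" else {"dna"}),
                     span, group_label=label) if n else None


class TestAssemble:
    @pytest.mark.parametrize("n,a,b,expected", [
        (20, 20, 0, "unchanged"),
        (20, 10, 9, "revised_rank1"),   # exactly 50%: A wins by threshold
        (20, 4, 7, "rank2"),
        (20, 4, 4, "revised_rank1"),    # tie prefers A
        (20, 0, 5, "rank2"),
        (20, 0, 0, "removed"),
        (20, 9, 0, "revised_rank1"),    # sub-threshold winner retained
    ])
    def test_threshold_and_dominance(self, n, a, b, expected):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(n)])
        out = assemble(ps, _candidate("A", a), _candidate("B", b, "dna_region"),
                       POLICY)
        assert out.status == expected

    def test_strict_threshold_removes_subhalf_winner(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(20)])
        policy = AssemblyPolicy(strict_threshold=True)
        out = assemble(ps, _candidate("A", 4), None, policy)
        assert out.status == "removed" and out.n_retained == 0

    def test_raising_threshold_never_revives_a_removed_set(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(10)])
        for a, b in [(0, 0), (3, 2), (5, 6)]:
            removed_low = []
            for thr in (0.3, 0.5, 0.8, 1.0):
                policy = AssemblyPolicy(retention_threshold=thr)
                out = assemble(ps, _candidate("A", a),
                               _candidate("B", b, "dna_region"), policy)
                removed_low.append(out.status == "removed")
            # once removed at some threshold, stays removed at higher ones
            assert removed_low == sorted(removed_low)

    def test_retention_fraction_reported(self):
        ps = ProbeSetRecord("s", [f"p{i}" for i in range(16)])
        out = assemble(ps, _candidate("A", 12), None, POLICY)
        assert out.retention_fraction == pytest.approx(0.75)


class TestSymbolSource:
    DB_TYPES = {"refseq": "transcript", "ensembl": "transcript",
                "nt": "collection", "dna": "genomic"}

    def _cand(self, kind, dbs, label="", symbol="S"):
        return Candidate(kind, ["p"], symbol, frozenset(dbs), None,
                         group_label=label)

    @pytest.mark.parametrize("dbs,expected", [
        (("refseq", "ensembl"), "refseq_and_ensembl"),
        (("refseq",), "refseq"),
        (("ensembl",), "ensembl"),
    ])
    def test_rank1_sources(self, dbs, expected):
        cand = self._cand("A", dbs)
        assert resolve_symbol_source(cand, self.DB_TYPES) == expected

    def test_collection_with_cooccurring_genomic_evidence(self):
        cand = self._cand("B", ("nt", "dna"), label="nt")
        assert resolve_symbol_source(cand, self.DB_TYPES) == "nt_and_dna"

    def test_collection_alone(self):
        cand = self._cand("B", ("nt",), label="nt")
        assert resolve_symbol_source(cand, self.DB_TYPES) == "nt"

    def test_anonymous_genomic_region(self):
        cand = self._cand("B", ("dna",), label="dna_region", symbol=None)
        assert resolve_symbol_source(cand, self.DB_TYPES) == "dna_region"
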