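"""Aggregation by genomic position, rank precedence and the Venn partition."""

import numpy as np
import pytest

from proberemap.models import (Alignment, CorrectedAlignment, GenomicFootprint,
                               ProbeClassification)
from proberemap.ranking import (aggregate_positions, classify_probe,
                                resolve_rank, venn_partition)


def _ca(db, target, chrom="chr1", strand="+", blocks=((100, 125),),
        known=True, start=0, pseudo=False):
    aln = Alignment("p", db, target, start, strand, ())
    fp = None if pseudo else GenomicFootprint(chrom, strand, blocks, known)
    return CorrectedAlignment(aln, fp, (), 0)


def _pos(chrom="chr1", known=True, pseudo=False, db="nt", target="acc",
         blocks=((100, 125),)):
    cas = [_ca(db, target, chrom=chrom, known=known, pseudo=pseudo,
               blocks=blocks)]
    return aggregate_positions(cas)[0]


class TestAggregation:
    def test_transcript_variants_sharing_footprint_merge(self):
        cas = [_ca("refseq", "tx1"), _ca("refseq", "tx1v2"), _ca("ensembl", "e1")]
        positions = aggregate_positions(cas)
        assert len(positions) == 1
        assert positions[0].supporting == {("refseq", "tx1", None),
                                           ("refseq", "tx1v2", None),
                                           ("ensembl", "e1", None)}

    def test_distinct_chromosomes_stay_distinct(self):
        cas = [_ca("refseq", "tx1", chrom="chr1"),
               _ca("refseq", "tx2", chrom="chr2")]
        assert len(aggregate_positions(cas)) == 2

    def test_collection_hits_form_pseudo_positions(self):
        cas = [_ca("nt", "acc1", pseudo=True, start=10),
               _ca("nt", "acc1", pseudo=True, start=60)]
        assert len(aggregate_positions(cas)) == 2

    def test_imperfect_hits_are_rejected(self):
        aln = Alignment("p", "db", "t", 0, "+", ())
        ca = CorrectedAlignment(
            Alignment("p", "db", "t", 0, "+",
                      (type("M", (), {"offset": 1, "probe_base": "A",
                                      "target_base": "C"})(),)),
            GenomicFootprint("chr1", "+", ((0, 25),), True), (), 0)
        with pytest.raises(ValueError):
            aggregate_positions([ca])

    def test_aggregation_equals_serialization_oracle(self):
        rng = np.random.default_rng(5)
        cas = []
        for k in range(60):
            chrom = f"chr{int(rng.integers(1, 4))}"
            s = int(rng.integers(0, 50)) * 100
            n_blocks = int(rng.integers(1, 3))
            if n_blocks == 1:
                blocks = ((s, s + 25),)
            else:
                blocks = ((s, s + 10), (s + 50, s + 65))
            cas.append(_ca("db", f"t{k}", chrom=chrom, blocks=blocks))
        positions = aggregate_positions(cas)
        oracle = {}
        for ca in cas:
            key = repr((ca.footprint.chrom, ca.footprint.strand,
                        ca.footprint.blocks))
            oracle.setdefault(key, set()).add(ca.alignment.target_id)
        assert len(positions) == len(oracle)
        assert sorted(len(p.supporting) for p in positions) == \
            sorted(len(v) for v in oracle.values())


class TestClassification:
    def test_single_rank1_position_is_transcript_specific(self):
        cl = classify_probe("p", {1: [_pos()]})
        assert cl.cls == "rank1_specific" and cl.rank == 1

    def test_rank1_multi_hit_terminates_processing(self):
        # two known-chromosome positions at rank 1: rank 2 is never
        # consulted even though it holds a clean unique position
        per_rank = {1: [_pos(chrom="chr1"), _pos(chrom="chr2")],
                    2: [_pos(chrom="chr3")]}
        cl = classify_probe("p", per_rank)
        assert cl.cls == "unspecific" and cl.rank == 1

    def test_multi_hit_fall_through_switch(self):
        per_rank = {1: [_pos(chrom="chr1"), _pos(chrom="chr2")],
                    2: [_pos(chrom="chr3")]}
        cl = classify_probe("p", per_rank, multi_hit_falls_through=True)
        assert cl.cls == "rank2_specific" and cl.rank == 2

    def test_no_rank1_hit_falls_through_to_rank2(self):
        cl = classify_probe("p", {1: [], 2: [_pos()]})
        assert cl.cls == "rank2_specific" and cl.rank == 2

    def test_unaligned_vs_imperfect(self):
        assert classify_probe("p", {1: []},
                              had_any_alignment=False).cls == "unaligned"
        cl = classify_probe("p", {1: []}, had_any_alignment=True)
        assert cl.cls == "unspecific" and cl.reason == "imperfect"

    def test_scaffold_positions_do_not_count_toward_multiplicity(self):
        # one known-chromosome position plus scaffolds: keep the known one
        per_rank = {1: [_pos(chrom="chr1"),
                        _pos(chrom="scaffold_1", known=False),
                        _pos(chrom="scaffold_2", known=False)]}
        cl = classify_probe("p", per_rank)
        assert cl.cls == "rank1_specific"
        assert cl.position.footprint.chrom == "chr1"

    def test_two_known_positions_unspecific_despite_scaffolds(self):
        per_rank = {1: [_pos(chrom="chr1"), _pos(chrom="chr2"),
                        _pos(chrom="scaffold_1", known=False)]}
        assert classify_probe("p", per_rank).cls == "unspecific"

    def test_single_scaffold_only_position_accepted(self):
        cl = classify_probe("p", {1: [_pos(chrom="scaffold_1", known=False)]})
        assert cl.cls == "rank1_specific"
        assert not cl.position.footprint.known_chromosome

    def test_multiple_scaffold_only_positions_ambiguous(self):
        per_rank = {1: [_pos(chrom="scaffold_1", known=False),
                        _pos(chrom="scaffold_2", known=False)]}
        cl = classify_probe("p", per_rank)
        assert cl.cls == "unspecific" and cl.reason == "ambiguous_scaffold"

    def test_single_collection_pseudo_position_is_specific(self):
        cl = classify_probe("p", {2: [_pos(pseudo=True)]})
        assert cl.cls == "rank2_specific"

    def test_two_collection_pseudo_positions_are_multi(self):
        cas = [_ca("nt", "acc1", pseudo=True, start=0),
               _ca("nt", "acc2", pseudo=True, start=0)]
        cl = classify_probe("p", {2: aggregate_positions(cas)})
        assert cl.cls == "unspecific"

    def test_collection_hit_supports_cooccurring_genomic_position(self):
        genomic = _pos(chrom="chr1", db="dna", target="chr1")
        pseudo = _pos(pseudo=True, db="nt", target="acc1")
        outcome = resolve_rank([genomic, pseudo])
        assert outcome[0] == "specific"
        assert ("nt", "acc1", None) in outcome[1].supporting


class TestVennPartition:
    def _cls(self, pid, venn):
        cl = ProbeClassification(pid, "rank1_specific")
        cl.venn_key = tuple(sorted(venn))
        return cl

    def test_counts_keyed_by_exact_db_set(self):
        cls = [self._cls("a", ("refseq", "ensembl")),
               self._cls("b", ("refseq", "ensembl")),
               self._cls("c", ("refseq",)),
               ProbeClassification("d", "unaligned")]
        venn = venn_partition(cls)
        assert venn == {("ensembl", "refseq"): 2, ("refseq",): 1}

    def test_partition_sums_to_probes_with_perfect_hits(self):
        rng = np.random.default_rng(12)
        dbs = ("refseq", "ensembl", "nt", "dna")
        cls = []
        n_with_hits = 0
        for i in range(200):
            mask = rng.random(4) < 0.4
            venn = tuple(d for d, m in zip(dbs, mask) if m)
            cl = ProbeClassification(f"p{i}", "rank1_specific")
            cl.venn_key = tuple(sorted(venn))
            cls.append(cl)
            n_with_hits += bool(venn)
        assert sum(venn_partition(cls).values()) == n_with_hits
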