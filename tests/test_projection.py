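"""Exon-chain projection, SNP forgiveness and footprint SNP counting."""

import itertools

import numpy as np
import pytest

from proberemap.models import (Alignment, GenomicFootprint, Mismatch,
                               SNPRecord, TranscriptModel, complement_base)
from proberemap.projection import (SnpIndex, correct_snps, count_snps,
                                   genomic_footprint_of_hit,
                                   project_to_genome, transcript_pos_to_genome)

KNOWN = frozenset({"chr1"})


def _aln(start, mismatches=(), strand="+", target="tx"):
    return Alignment("p", "db", target, start, strand, tuple(mismatches))


class TestProjection:
    def test_single_exon_plus_strand_offset(self):
        tm = TranscriptModel("tx", "chr1", "+", [(1000, 1150)])
        fp = project_to_genome(_aln(10), 25, tm, KNOWN)
        assert fp.blocks == ((1010, 1035),)
        assert fp.strand == "+" and fp.known_chromosome

    def test_junction_spanning_probe_splits_blocks(self):
        tm = TranscriptModel("tx", "chr1", "+", [(100, 120), (300, 400)])
        fp = project_to_genome(_aln(10), 25, tm, KNOWN)
        assert fp.blocks == ((110, 120), (300, 315))

    def test_minus_strand_mirrors_coordinates(self):
        # transcription order on '-': highest-coordinate exon first
        tm = TranscriptModel("tx", "chr1", "-", [(300, 400), (100, 120)])
        fp = project_to_genome(_aln(0), 25, tm, KNOWN)
        # transcript offset 0 maps to genomic position 399
        assert fp.blocks == ((375, 400),)
        assert fp.strand == "-"

    def test_alignment_past_exon_chain_is_fatal(self):
        tm = TranscriptModel("tx", "chr1", "+", [(0, 30)])
        with pytest.raises(ValueError, match="past transcript"):
            project_to_genome(_aln(10), 25, tm, KNOWN)

    def test_blocks_agree_with_per_base_walking_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_exons = int(rng.integers(1, 5))
            exons_fwd, pos = [], int(rng.integers(0, 1000))
            for _ in range(n_exons):
                ln = int(rng.integers(30, 120))
                exons_fwd.append((pos, pos + ln))
                pos += ln + int(rng.integers(20, 200))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = exons_fwd if strand == "+" else exons_fwd[::-1]
            tm = TranscriptModel("tx", "chr1", strand, exons)
            L = 25
            start = int(rng.integers(0, tm.length - L + 1))
            fp = project_to_genome(_aln(start), L, tm, KNOWN)
            # oracle: walk the chain one base at a time
            walked = sorted(transcript_pos_to_genome(tm, start + k)
                            for k in range(L))
            covered = sorted(g for s, e in fp.blocks for g in range(s, e))
            assert walked == covered

    def test_projection_is_invertible_on_block_bases(self):
        tm = TranscriptModel("tx", "chr1", "-", [(500, 560), (100, 140)])
        start = 50
        fp = project_to_genome(_aln(start), 25, tm, KNOWN)
        genomic = [transcript_pos_to_genome(tm, start + k) for k in range(25)]
        assert sorted(genomic) == sorted(
            g for s, e in fp.blocks for g in range(s, e))


class TestSnpCorrection:
    def _setup_plus(self):
        tm = TranscriptModel("tx", "chr1", "+", [(1000, 1100)])
        return tm

    def test_forgiven_when_alt_allele_matches(self):
        tm = self._setup_plus()
        aln = _aln(10, [Mismatch(5, "G", "A")])
        fp = project_to_genome(aln, 25, tm, KNOWN)
        snps = SnpIndex([SNPRecord("chr1", 1015, "A", frozenset({"G"}))])
        ca = correct_snps(aln, fp, snps, model=tm)
        assert ca.effective_mm == 0 and ca.forgiven == (5,)

    def test_not_forgiven_without_snp(self):
        tm = self._setup_plus()
        aln = _aln(10, [Mismatch(5, "G", "A")])
        fp = project_to_genome(aln, 25, tm, KNOWN)
        ca = correct_snps(aln, fp, SnpIndex([]), model=tm)
        assert ca.effective_mm == 1 and ca.forgiven == ()

    def test_strict_mode_requires_allele_match(self):
        tm = self._setup_plus()
        aln = _aln(10, [Mismatch(5, "G", "A")])
        fp = project_to_genome(aln, 25, tm, KNOWN)
        snps = SnpIndex([SNPRecord("chr1", 1015, "A", frozenset({"T"}))])
        strict = correct_snps(aln, fp, snps, allele_strict=True, model=tm)
        relaxed = correct_snps(aln, fp, snps, allele_strict=False, model=tm)
        assert strict.effective_mm == 1
        assert relaxed.effective_mm == 0

    def test_minus_strand_probe_base_compared_in_plus_frame(self):
        # '-' strand transcript: probe base G at transcript offset maps to C
        # on the genomic plus strand
        tm = TranscriptModel("tx", "chr1", "-", [(1000, 1100)])
        aln = _aln(0, [Mismatch(5, "G", "A")])
        fp = project_to_genome(aln, 25, tm, KNOWN)
        gpos = transcript_pos_to_genome(tm, 5)
        forgiving = SnpIndex([SNPRecord("chr1", gpos, "T", frozenset({"C"}))])
        wrong = SnpIndex([SNPRecord("chr1", gpos, "T", frozenset({"G"}))])
        assert correct_snps(aln, fp, forgiving, model=tm).effective_mm == 0
        assert correct_snps(aln, fp, wrong, model=tm).effective_mm == 1

    def test_exhaustive_two_mismatch_allele_scenarios(self):
        """Enumerate allele configurations against the longhand rule."""
        tm = self._setup_plus()
        offsets = (3, 17)
        cases = ["none", "ref", "alt", "other"]  # SNP situation at each site
        for c1, c2 in itertools.product(cases, repeat=2):
            mms = [Mismatch(offsets[0], "G", "A"), Mismatch(offsets[1], "C", "T")]
            aln = _aln(0, mms)
            fp = project_to_genome(aln, 25, tm, KNOWN)
            records = []
            for off, case, probe_base, tgt in zip(
                    offsets, (c1, c2), ("G", "C"), ("A", "T")):
                gpos = 1000 + off
                if case == "none":
                    continue
                if case == "ref":  # probe base equals the recorded reference
                    records.append(SNPRecord("chr1", gpos, probe_base,
                                             frozenset({"A"})))
                elif case == "alt":
                    records.append(SNPRecord("chr1", gpos, tgt,
                                             frozenset({probe_base})))
                else:  # SNP present but with an incompatible allele
                    records.append(SNPRecord("chr1", gpos, tgt,
                                             frozenset({tgt})))
            snps = SnpIndex(records)
            strict = correct_snps(aln, fp, snps, allele_strict=True, model=tm)
            relaxed = correct_snps(aln, fp, snps, allele_strict=False, model=tm)
            exp_strict = sum(c in ("ref", "alt") for c in (c1, c2))
            exp_relaxed = sum(c != "none" for c in (c1, c2))
            assert len(strict.forgiven) == exp_strict
            assert len(relaxed.forgiven) == exp_relaxed
            assert strict.effective_mm == 2 - exp_strict
            assert relaxed.effective_mm == 2 - exp_relaxed

    def test_adding_snps_never_increases_effective_mm(self):
        rng = np.random.default_rng(3)
        tm = self._setup_plus()
        base_records = [SNPRecord("chr1", 1005, "A", frozenset({"G"}))]
        extra = [SNPRecord("chr1", int(p), "A", frozenset({"G", "T", "C"}))
                 for p in rng.integers(1000, 1100, 20)]
        aln = _aln(0, [Mismatch(5, "G", "A"), Mismatch(9, "T", "C")])
        fp = project_to_genome(aln, 25, tm, KNOWN)
        small = correct_snps(aln, fp, SnpIndex(base_records), model=tm)
        large = correct_snps(aln, fp, SnpIndex(base_records + extra), model=tm)
        assert large.effective_mm <= small.effective_mm


class TestSnpCounting:
    def test_half_open_boundary_convention(self):
        fp = GenomicFootprint("chr1", "+", ((100, 125),), True)
        at_start = SnpIndex([SNPRecord("chr1", 100, "A", frozenset({"G"}))])
        at_end = SnpIndex([SNPRecord("chr1", 125, "A", frozenset({"G"}))])
        assert count_snps(fp, at_start) == 1
        assert count_snps(fp, at_end) == 0

    def test_empty_index_counts_zero(self):
        fp = GenomicFootprint("chr1", "+", ((0, 25),), True)
        assert count_snps(fp, SnpIndex([])) == 0

    def test_counts_match_membership_oracle(self):
        rng = np.random.default_rng(9)
        records = [SNPRecord("chr1", int(p), "A", frozenset({"C"}))
                   for p in rng.choice(5000, size=800, replace=False)]
        snps = SnpIndex(records)
        positions = {r.pos for r in records}
        for _ in range(100):
            s = int(rng.integers(0, 4000))
            blocks = ((s, s + 10), (s + 40, s + 55))
            fp = GenomicFootprint("chr1", "+", blocks, True)
            expected = sum(1 for p in positions
                           if any(a <= p < b for a, b in blocks))
            assert count_snps(fp, snps) == expected

    def test_genomic_hit_footprint_is_single_block(self):
        aln = _aln(100, strand="-", target="chr1")
        fp = genomic_footprint_of_hit(aln, 25, KNOWN)
        assert fp.blocks == ((100, 125),) and fp.strand == "-"
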