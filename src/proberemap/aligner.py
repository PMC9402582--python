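"""Ungapped best-stratum alignment of fixed-length probes.

The contract mirrors the classic short-read aligner behaviour for short
oligos: report *all* ungapped hits whose mismatch count equals the
minimum achievable for the probe in that database (the "best stratum"),
up to a per-database cap ``v`` of 0-2 mismatches, optionally searching
the reverse complement.

The search is exact by pigeonhole seeding: the probe is partitioned into
``v + 1`` contiguous seeds, so any alignment with at most ``v``
mismatches leaves at least one seed mismatch-free.  Every seed-length
substring of every target is indexed; candidate windows found through a
seed are then verified base by base.  This is exhaustive by
construction: no heuristic backtracking limits apply.

Targets may contain non-ACGT characters; an ambiguity code never matches
a probe base (it always counts as a mismatch, and seeds overlapping it
cannot anchor a hit).
"""

from __future__ import annotations

import numpy as np

from .models import Alignment, AlignmentPolicy, Mismatch, ProbeRecord, ReferenceDB, revcomp

__all__ = ["seed_partition", "SeedIndex", "build_index", "align_probe",
           "brute_force_align"]

_ORACLE_MAX_DB = 1_000_000  # total target bases the brute-force oracle accepts


def seed_partition(probe_length: int, max_mismatches: int) -> list[tuple[int, int]]:
    """Partition ``[0, L)`` into ``v + 1`` contiguous seeds.

    Returns a list of ``(offset, length)`` pairs; the remainder goes to
    the leftmost seeds, so L=25, v=2 gives lengths 9, 8, 8.
    """
    k = max_mismatches + 1
    if probe_length < k:
        raise ValueError(
            f"cannot split probe of length {probe_length} into {k} non-empty seeds")
    base, rem = divmod(probe_length, k)
    lengths = [base + 1] * rem + [base] * (k - rem)
    seeds, off = [], 0
    for ln in lengths:
        seeds.append((off, ln))
        off += ln
    return seeds


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of all k-mers of ``seq``; -1 where a window has non-ACGT."""
    vals = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(vals)
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows @ powers
    codes[(windows < 0).any(axis=1)] = -1
    return codes


def _encode_kmer(seq: str) -> int:
    code = 0
    for c in seq:
        code = code * 4 + int(_CODE[ord(c)])
    return code


class SeedIndex:
    """Exact-match lookup over all seed-length substrings of a database.

    Substrings are stored as 2-bit integer codes; windows overlapping an
    ambiguity code are not indexed (they can never match an ACGT probe).
    """

    def __init__(self, db: ReferenceDB, probe_length: int):
        self.db = db
        self.probe_length = probe_length
        self.seeds = seed_partition(probe_length, db.policy.max_mismatches)
        self._target_ids = list(db.sequences)
        # per seed length: (sorted k-mer codes, parallel packed locators)
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        lengths = sorted({ln for _, ln in self.seeds})
        for ln in lengths:
            code_parts, loc_parts = [], []
            for t_idx, target_id in enumerate(self._target_ids):
                codes = _kmer_codes(db.sequences[target_id], ln)
                keep = np.flatnonzero(codes >= 0)
                if not len(keep):
                    continue
                code_parts.append(codes[keep])
                # pack (target index, position) into one int64 locator
                loc_parts.append((np.int64(t_idx) << 40) | keep.astype(np.int64))
            if code_parts:
                codes = np.concatenate(code_parts)
                locs = np.concatenate(loc_parts)
                order = np.argsort(codes, kind="stable")
                self._tables[ln] = (codes[order], locs[order])
            else:
                self._tables[ln] = (np.empty(0, dtype=np.int64),
                                    np.empty(0, dtype=np.int64))

    def candidate_starts(self, seq: str):
        """(target_id, window_start) for every seed hit of ``seq``."""
        L = self.probe_length
        out = set()
        for off, ln in self.seeds:
            code = _encode_kmer(seq[off:off + ln])
            codes, locs = self._tables[ln]
            lo = np.searchsorted(codes, code, side="left")
            hi = np.searchsorted(codes, code, side="right")
            for loc in locs[lo:hi].tolist():
                t_idx, pos = loc >> 40, loc & ((1 << 40) - 1)
                start = pos - off
                target_id = self._target_ids[t_idx]
                if start >= 0 and start + L <= len(self.db.sequences[target_id]):
                    out.add((target_id, start))
        return out


def build_index(db: ReferenceDB, probe_length: int) -> SeedIndex:
    return SeedIndex(db, probe_length)


def _verify(probe_id: str, db_name: str, oriented: str, target_id: str,
            target_seq: str, start: int, strand: str, v: int):
    """Compare an oriented probe to a target window; None if > v mismatches."""
    window = target_seq[start:start + len(oriented)]
    mms = []
    for i, (p, t) in enumerate(zip(oriented, window)):
        if p != t:
            mms.append(Mismatch(i, p, t))
            if len(mms) > v:
                return None
    return Alignment(probe_id, db_name, target_id, start, strand, tuple(mms))


def align_probe(probe: ProbeRecord, index: SeedIndex,
                policy: AlignmentPolicy | None = None) -> list[Alignment]:
    """All best-stratum ungapped hits of a probe in one database.

    Returns every alignment whose mismatch count equals the minimum
    achievable for this probe in this database (empty if nothing aligns
    within the cap), sorted by (target, start, strand).  Reverse
    complement hits are reported in target-forward coordinates with
    strand '-' and probe bases complemented into that frame.
    """
    if policy is None:
        policy = index.db.policy
    v = policy.max_mismatches
    seqs = index.db.sequences
    hits: list[Alignment] = []
    searches = [(probe.sequence, "+")]
    if policy.allow_reverse_complement:
        searches.append((revcomp(probe.sequence), "-"))
    for oriented, strand in searches:
        for target_id, start in index.candidate_starts(oriented):
            aln = _verify(probe.probe_id, index.db.name, oriented, target_id,
                          seqs[target_id], start, strand, v)
            if aln is not None:
                hits.append(aln)
    if not hits:
        return []
    best = min(a.raw_mm for a in hits)
    return sorted((a for a in hits if a.raw_mm == best),
                  key=Alignment.sort_key)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def brute_force_align(probe: ProbeRecord, db: ReferenceDB,
                      policy: AlignmentPolicy | None = None) -> list[Alignment]:
    """Exhaustive Hamming scan over every window and strand.

    Same contract as :func:`align_probe`; intended as an independent
    oracle on small databases (guarded at 1 Mb total).
    """
    if policy is None:
        policy = db.policy
    total = sum(len(s) for s in db.sequences.values())
    if total > _ORACLE_MAX_DB:
        raise ValueError(f"brute-force oracle guard exceeded: {total} bases")
    v = policy.max_mismatches
    L = len(probe.sequence)
    searches = [(probe.sequence, "+")]
    if policy.allow_reverse_complement:
        searches.append((revcomp(probe.sequence), "-"))
    hits: list[Alignment] = []
    for target_id, seq in db.sequences.items():
        if len(seq) < L:
            continue
        arr = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for oriented, strand in searches:
            mm_counts = (windows != _encode(oriented)).sum(axis=1)
            for start in np.flatnonzero(mm_counts <= v):
                start = int(start)
                window = seq[start:start + L]
                mms = tuple(Mismatch(i, p, t)
                            for i, (p, t) in enumerate(zip(oriented, window))
                            if p != t)
                hits.append(Alignment(probe.probe_id, db.name, target_id,
                                      start, strand, mms))
    if not hits:
        return []
    best = min(a.raw_mm for a in hits)
    return sorted((a for a in hits if a.raw_mm == best),
                  key=Alignment.sort_key)
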