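"""Greedy suffix-prefix overlap assembly at fixture scale.

The assembler repeatedly merges the pair of sequences with the longest
suffix-prefix overlap (both strands considered) until no overlap of at
least ``min_overlap`` remains; sequences fully contained in another are
absorbed.  Overlap candidates are seeded by any exact 20-mer shared
between two sequences - the offset pair of a shared seed fixes the
implied overlap length - and verified over the full overlap allowing up
to ``max_mismatch_rate`` mismatching positions.  Ties in overlap length
are broken by the lexicographically smallest merged sequence; final
contigs are reported on their canonical strand (the lexicographically
smaller of sequence / reverse complement), so assembly is deterministic
and invariant to read input order up to contig naming.

This is deliberately a small overlap-layout assembler: the discovery
rules downstream (length filter, domain content, phylotype
dereplication) are the object of interest, not assembly engineering.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .synthetic_community import revcomp, write_fasta


@dataclass
class Contig:
    id: str
    sequence: str
    n_reads: int
    source_dataset: str = "dataset"
    read_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


_SEED_K = 20      # exact-seed length; shorter than min_overlap so a single
                  # sequencing error cannot hide a verifiable overlap
_INDEX_STRIDE = 2  # windows are indexed every other position; scanning is
                   # dense, so any clean shared 21-mer still seeds


def _encode_kmer(s: str) -> int | None:
    v = 0
    for c in s:
        b = "ACGT".find(c)
        if b < 0:
            return None
        v = (v << 2) | b
    return v


class _Pool:
    """Live sequences plus the shared-window index the greedy loop uses."""

    def __init__(self, k: int):
        self.k = k
        self.seqs: dict[int, str] = {}
        self.reads: dict[int, list[str]] = {}
        self.windows: dict[int, list[int]] = {}  # kmer -> packed entries
        self.next_id = 0
        self._indexed_entries = 0
        self._live_entries = 0

    # entries are packed as (cid << 33) | (orient_bit << 32) | pos
    @staticmethod
    def _pack(cid: int, orient: int, pos: int) -> int:
        return (cid << 33) | ((1 if orient < 0 else 0) << 32) | pos

    @staticmethod
    def _unpack(v: int) -> tuple[int, int, int]:
        return v >> 33, -1 if (v >> 32) & 1 else 1, v & 0xFFFFFFFF

    def oriented(self, cid: int, orient: int) -> str:
        s = self.seqs[cid]
        return s if orient > 0 else revcomp(s)

    def _n_entries(self, seq: str) -> int:
        return 2 * max(0, (len(seq) - self.k) // _INDEX_STRIDE + 1)

    def _index(self, cid: int, seq: str) -> None:
        k = self.k
        for orient in (1, -1):
            s = seq if orient > 0 else revcomp(seq)
            for p in range(0, len(s) - k + 1, _INDEX_STRIDE):
                code = _encode_kmer(s[p : p + k])
                if code is not None:
                    self.windows.setdefault(code, []).append(
                        self._pack(cid, orient, p)
                    )
        self._indexed_entries += self._n_entries(seq)
        self._live_entries += self._n_entries(seq)

    def add(self, seq: str, read_ids: list[str]) -> int:
        cid = self.next_id
        self.next_id += 1
        self.seqs[cid] = seq
        self.reads[cid] = read_ids
        self._index(cid, seq)
        return cid

    def remove(self, cid: int) -> None:
        self._live_entries -= self._n_entries(self.seqs[cid])
        del self.seqs[cid]
        del self.reads[cid]
        # stale index entries are filtered lazily; rebuild when bloated
        if self._indexed_entries > 4 * max(self._live_entries, 1):
            self.windows = {}
            self._indexed_entries = 0
            self._live_entries = 0
            for c, s in self.seqs.items():
                self._index(c, s)

    def alive(self, cid: int) -> bool:
        return cid in self.seqs


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _scan_candidates(pool: _Pool, cid: int) -> Iterator[tuple[int, int, int, int, int]]:
    """Overlap candidates ``(left_id, left_orient, right_id, right_orient,
    overlap)`` implied by k-mers shared between ``cid`` (stored
    orientation) and any other live sequence (either orientation)."""
    a = pool.seqs[cid]
    k = pool.k
    seen: set[tuple[int, int, int, int, int]] = set()
    for p_a in range(len(a) - k + 1):
        code = _encode_kmer(a[p_a : p_a + k])
        if code is None:
            continue
        entries = pool.windows.get(code)
        if not entries:
            continue
        for packed in entries:
            bid, orient, p_b = pool._unpack(packed)
            if bid == cid or not pool.alive(bid):
                continue
            if p_b <= p_a:
                cand = (cid, 1, bid, orient, len(a) - p_a + p_b)
            else:
                cand = (bid, orient, cid, 1, len(pool.seqs[bid]) - p_b + p_a)
            if cand not in seen:
                seen.add(cand)
                yield cand


def _verify(pool: _Pool, cand, max_mismatch_rate: float, min_overlap: int):
    """Return (overlap_len, merged_sequence) or None."""
    aid, a_orient, bid, b_orient, o = cand
    if not (pool.alive(aid) and pool.alive(bid)):
        return None
    a = pool.oriented(aid, a_orient)
    b = pool.oriented(bid, b_orient)
    if o < min_overlap or o > len(a):
        return None
    eff = min(o, len(b))
    limit = int(max_mismatch_rate * eff)
    if _count_mismatches(a[len(a) - o : len(a) - o + eff], b[:eff], limit) > limit:
        return None
    if o >= len(b):
        return (len(b), a)  # b is contained in a
    return (o, a + b[o:])


def greedy_assemble(
    reads: Sequence[tuple[str, str]],
    min_overlap: int = 30,
    max_mismatch_rate: float = 0.0,
    source_dataset: str = "dataset",
) -> list[Contig]:
    """Assemble reads by longest-overlap-first greedy merging.

    ``reads`` is a sequence of ``(read_id, sequence)``.  Unmergeable reads
    emerge as singleton contigs.
    """
    if not reads:
        raise ValueError("at least one read is required")
    pool = _Pool(min(_SEED_K, min_overlap))

    # absorb exact duplicates / reverse-complement duplicates up front
    seen_seq: dict[str, int] = {}
    for rid, seq in reads:
        seq = seq.upper()
        canon = min(seq, revcomp(seq))
        if canon in seen_seq:
            pool.reads[seen_seq[canon]].append(rid)
        else:
            cid = pool.add(seq, [rid])
            seen_seq[canon] = cid

    heap: list[tuple[int, int, int, int, int, int]] = []

    def push_candidates(cid: int) -> None:
        for cand in _scan_candidates(pool, cid):
            res = _verify(pool, cand, max_mismatch_rate, min_overlap)
            if res:
                heapq.heappush(heap, (-res[0], *cand))

    for cid in list(pool.seqs):
        push_candidates(cid)

    while heap:
        neg_o, *cand_list = heapq.heappop(heap)
        cand = tuple(cand_list)
        res = _verify(pool, cand, max_mismatch_rate, min_overlap)
        if res is None or res[0] != -neg_o:
            continue
        # ties at this overlap length: lexicographically smallest merge
        group = [(res[1], cand)]
        stash = []
        while heap and heap[0][0] == neg_o:
            other = heapq.heappop(heap)
            ocand = tuple(other[1:])
            ores = _verify(pool, ocand, max_mismatch_rate, min_overlap)
            if ores is not None and ores[0] == -neg_o:
                group.append((ores[1], ocand))
                stash.append(other)
        group.sort(key=lambda t: t[0])
        merged_seq, chosen = group[0]
        for item in stash:
            if tuple(item[1:]) != chosen:
                heapq.heappush(heap, item)
        if chosen != cand:
            heapq.heappush(heap, (neg_o, *cand))

        aid, _, bid, _, _ = chosen
        read_ids = pool.reads[aid] + pool.reads[bid]
        pool.remove(aid)
        pool.remove(bid)
        new_cid = pool.add(merged_seq, read_ids)
        push_candidates(new_cid)

    contigs = []
    for cid, seq in pool.seqs.items():
        canon = min(seq, revcomp(seq))
        contigs.append((canon, pool.reads[cid]))
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(
            id=f"contig{i:05d}",
            sequence=seq,
            n_reads=len(rids),
            source_dataset=source_dataset,
            read_ids=sorted(rids),
        )
        for i, (seq, rids) in enumerate(contigs)
    ]


def filter_contigs(contigs: Iterable[Contig], min_len: int = 750) -> list[Contig]:
    """Retain contigs strictly longer than ``min_len`` nucleotides."""
    return [c for c in contigs if len(c.sequence) > min_len]


def write_contigs_fasta(contigs: Sequence[Contig], path) -> None:
    write_fasta(
        [(f"{c.id} n_reads={c.n_reads}", c.sequence) for c in contigs], path
    )
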