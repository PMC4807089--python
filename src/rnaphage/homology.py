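"""Translated homology triage: a tBLASTn-like search of nucleotide reads
against reference phage proteins.

Reads are translated in all six frames; 3-mer neighborhood words seed
candidate read/protein pairs which are then scored by Smith-Waterman local
alignment (BLOSUM62, affine gaps).  E-values follow the Karlin-Altschul
form ``E = m * n * 2**(-bits)`` with the database size taken as the total
number of translated letters across all six frames of all reads.  Datasets
are selected for assembly when at least ``min_reads`` *distinct* reads
align below the E-value cutoff (default 1e-4).

Exact agreement with NCBI BLAST statistics is not a goal; internal
ordering and thresholding consistency is.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")
_STD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STD_IDX = {c: i for i, c in enumerate(_STD_AA)}
_B62_20 = np.array(
    [[_B62[a][b] for b in _STD_AA] for a in _STD_AA], dtype=np.float64
)

FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six reading frames of a nucleotide sequence.

    Frames +1..+3 come from the forward strand at offsets 0..2, frames
    -1..-3 from the reverse complement at offsets 0..2.  Trailing partial
    codons are dropped; codons containing ambiguity become ``X``; stop
    codons are rendered ``*``.  Sequences shorter than one codon yield
    empty frames (with a warning).
    """
    s = seq.upper().replace("U", "T")
    if len(s) < 3:
        warnings.warn("sequence shorter than one codon: empty translation")
        return {f: "" for f in FRAMES}
    rc = str(Seq(s).reverse_complement())
    out: dict[int, str] = {}
    for off in range(3):
        for frame, src in ((off + 1, s), (-(off + 1), rc)):
            sub = src[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            out[frame] = str(Seq(sub).translate()) if sub else ""
    return out


@dataclass(frozen=True)
class TranslatedHit:
    """One read-vs-protein local alignment (translated coordinates)."""

    read_id: str
    query_protein_id: str
    frame: int
    raw_score: int
    bit_score: float
    e_value: float
    read_start: int
    read_end: int
    query_start: int
    query_end: int


@dataclass(frozen=True)
class TriageDecision:
    dataset_id: str
    n_significant_reads: int
    selected: bool


@dataclass
class SearchParams:
    word_size: int = 3
    seed_threshold: float = 13.0   # neighborhood word score cutoff
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267   # BLOSUM62 / 11 / 1
    karlin_k: float = 0.041
    min_raw_score: float = 1.0


def bit_score(raw: float, params: SearchParams) -> float:
    return (params.karlin_lambda * raw - math.log(params.karlin_k)) / math.log(2.0)


def e_value(raw: float, query_len: int, db_letters: int, params: SearchParams) -> float:
    return query_len * db_letters * 2.0 ** (-bit_score(raw, params))


def _aligner(params: SearchParams, mode: str = "local") -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _B62
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -params.gap_extend
    return al


def _neighborhood_index(
    queries: Sequence[tuple[str, str]], params: SearchParams
) -> dict[tuple[int, ...], set[str]]:
    """word (as residue-index tuple) -> query ids having a word within
    BLOSUM62 score >= seed_threshold of it.  Words containing non-standard
    residues never seed."""
    w = params.word_size
    index: dict[tuple[int, ...], set[str]] = {}
    rng20 = np.arange(20)
    for qid, prot in queries:
        enc = np.array([_STD_IDX.get(c, -1) for c in prot.upper()], dtype=np.int64)
        for p in range(len(enc) - w + 1):
            word = enc[p : p + w]
            if (word < 0).any():
                continue
            # scores of all 20^w words against this query word
            score = _B62_20[word[0]][:, None, None] \
                + _B62_20[word[1]][None, :, None] \
                + _B62_20[word[2]][None, None, :]
            for i, j, k in np.argwhere(score >= params.seed_threshold):
                index.setdefault((int(i), int(j), int(k)), set()).add(qid)
    return index


def translated_search(
    queries: Sequence[tuple[str, str]] | dict[str, str],
    reads: Sequence[tuple[str, str]] | dict[str, str],
    params: SearchParams | None = None,
    evalue_cutoff: float | None = None,
) -> list[TranslatedHit]:
    """Seeded translated local search of reads against protein queries.

    Returns hits sorted by (read_id, query id, frame); when
    ``evalue_cutoff`` is given only hits strictly below it are kept.
    An empty translated database yields an empty result.
    """
    params = params or SearchParams()
    qitems = list(queries.items()) if isinstance(queries, dict) else list(queries)
    ritems = list(reads.items()) if isinstance(reads, dict) else list(reads)
    if not qitems:
        raise ValueError("no query proteins supplied")

    frames_by_read = {rid: six_frame_translate(seq) for rid, seq in ritems}
    db_letters = sum(
        len(f) for frames in frames_by_read.values() for f in frames.values()
    )
    if db_letters == 0:
        return []

    index = _neighborhood_index(qitems, params)
    qlen = {qid: len(prot) for qid, prot in qitems}
    qprot = dict(qitems)
    aligner = _aligner(params)
    w = params.word_size

    hits: list[TranslatedHit] = []
    for rid, _ in ritems:
        for frame in FRAMES:
            faa = frames_by_read[rid][frame]
            if len(faa) < w:
                continue
            enc = [_STD_IDX.get(c, -1) for c in faa]
            candidates: set[str] = set()
            for p in range(len(enc) - w + 1):
                word = tuple(enc[p : p + w])
                if -1 in word:
                    continue
                got = index.get(word)
                if got:
                    candidates |= got
                    if len(candidates) == len(qitems):
                        break
            for qid in sorted(candidates):
                raw = aligner.score(faa, qprot[qid])
                if raw < params.min_raw_score:
                    continue
                ev = e_value(raw, qlen[qid], db_letters, params)
                if evalue_cutoff is not None and not (ev < evalue_cutoff):
                    continue
                aln = next(iter(aligner.align(faa, qprot[qid])))
                tblocks, qblocks = aln.aligned
                hits.append(
                    TranslatedHit(
                        read_id=rid,
                        query_protein_id=qid,
                        frame=frame,
                        raw_score=int(raw),
                        bit_score=bit_score(raw, params),
                        e_value=ev,
                        read_start=int(tblocks[0][0]),
                        read_end=int(tblocks[-1][1]),
                        query_start=int(qblocks[0][0]),
                        query_end=int(qblocks[-1][1]),
                    )
                )
    hits.sort(key=lambda h: (h.read_id, h.query_protein_id, h.frame))
    return hits


def triage_dataset(
    hits: Iterable[TranslatedHit],
    dataset_id: str = "dataset",
    min_reads: int = 10,
    evalue_cutoff: float = 1e-4,
) -> TriageDecision:
    """Select a dataset for assembly when at least ``min_reads`` distinct
    reads have >= 1 hit with E-value strictly below the cutoff."""
    significant = {h.read_id for h in hits if h.e_value < evalue_cutoff}
    n = len(significant)
    return TriageDecision(dataset_id, n, n >= min_reads)


def write_hits_tsv(hits: Sequence[TranslatedHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tquery_id\tframe\traw\tbits\tevalue\t"
            "read_start\tread_end\tquery_start\tquery_end\n"
        )
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.query_protein_id}\t{h.frame:+d}\t{h.raw_score}\t"
                f"{h.bit_score:.2f}\t{h.e_value:.3g}\t{h.read_start}\t{h.read_end}\t"
                f"{h.query_start}\t{h.query_end}\n"
            )


def write_triage_json(decision: TriageDecision, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "dataset_id": decision.dataset_id,
                "n_significant_reads": decision.n_significant_reads,
                "selected": decision.selected,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
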