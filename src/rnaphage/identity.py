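"""Pairwise global alignment and percent-identity matrices.

Identity here is the p-distance convention used throughout the pipeline:
a Needleman-Wunsch global alignment is computed with affine gap costs, and
identity is the fraction of identical columns among columns where *both*
sequences carry a residue (pairwise gap deletion).  Gaps therefore never
count as mismatches; ``mismatches`` is the number of aligned-residue
columns that differ.

The alignment itself is a Gotoh three-state dynamic program with a fixed,
documented tie-break so that results are reproducible: at equal score a
substitution step is preferred over a gap in the second sequence, which is
preferred over a gap in the first.

Default scoring
---------------
nucleotide : match +2, mismatch -3, gap open 10, gap extend 4
             (a gap of length k costs 10 + 4k).  Gap costs are kept well
             above the mismatch cost: with pairwise gap deletion, cheap
             gaps would let the optimum shed mismatch-dense columns into
             gap columns and inflate the identity of highly divergent
             pairs, right where the 70% phylotype rule discriminates.
amino acid : BLOSUM62, gap open 11, gap extend 1 (a gap of length k
             costs 11 + k)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e18

# traceback states
_M, _X, _Y = 0, 1, 2


def _blosum62_lookup() -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load("BLOSUM62")
    alpha = str(mat.alphabet)
    idx = {c: i for i, c in enumerate(alpha)}
    return np.asarray(mat, dtype=np.float64), idx


_B62, _B62_IDX = _blosum62_lookup()


def _encode(seq: str, alphabet: str) -> np.ndarray:
    s = seq.upper()
    if alphabet == "nt":
        table = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
        return np.array([table.get(c, 4) for c in s], dtype=np.int64)
    return np.array([_B62_IDX.get(c, _B62_IDX["X"]) for c in s], dtype=np.int64)


def _score_matrix(alphabet: str, match: float, mismatch: float) -> np.ndarray:
    if alphabet == "aa":
        return _B62
    # 5 symbols: A C G T N ; N mismatches everything including itself
    m = np.full((5, 5), mismatch, dtype=np.float64)
    for i in range(4):
        m[i, i] = match
    return m


@dataclass(frozen=True)
class AlignmentIdentity:
    """Identity summary of one global alignment."""

    identity: float
    mismatches: int
    aligned_positions: int
    score: float
    aligned_a: str = ""
    aligned_b: str = ""


def global_align_identity(
    a: str,
    b: str,
    alphabet: str = "nt",
    *,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float | None = None,
    gap_extend: float | None = None,
    keep_alignment: bool = False,
) -> AlignmentIdentity:
    """Globally align two sequences and report p-distance identity.

    Parameters
    ----------
    alphabet : ``"nt"`` or ``"aa"``.  Amino-acid mode scores with BLOSUM62.
    gap_open, gap_extend : affine gap costs (positive numbers); a gap of
        length ``k`` costs ``gap_open + k * gap_extend``.

    Returns an :class:`AlignmentIdentity`; ``identity`` equals
    ``1 - mismatches / aligned_positions`` over gap-free columns.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if gap_open is None:
        gap_open = 10.0 if alphabet == "nt" else 11.0
    if gap_extend is None:
        gap_extend = 4.0 if alphabet == "nt" else 1.0
    open1 = gap_open + gap_extend  # cost of the first gapped position
    ext = gap_extend

    ea, eb = _encode(a, alphabet), _encode(b, alphabet)
    S = _score_matrix(alphabet, match, mismatch)
    n, m = len(ea), len(eb)

    # rows: i over a (0..n), cols: j over b (0..m)
    M_prev = np.full(m + 1, NEG)
    X_prev = np.full(m + 1, NEG)
    Y_prev = np.full(m + 1, NEG)
    M_prev[0] = 0.0
    js = np.arange(1, m + 1, dtype=np.float64)
    Y_prev[1:] = -open1 - (js - 1) * ext

    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY[0, 1:] = 1  # leading gap row extends itself

    for i in range(1, n + 1):
        sub = S[ea[i - 1], eb]  # scores vs every b residue, length m
        # M from previous row diagonal; tie order M > X > Y
        diag = np.vstack((M_prev[:-1], X_prev[:-1], Y_prev[:-1]))
        best_prev = diag.max(axis=0)
        ptrM[i, 1:] = diag.argmax(axis=0)  # argmax takes first on ties
        M_row = np.full(m + 1, NEG)
        M_row[1:] = sub + best_prev

        # X: gap in b (vertical), from previous row same column
        fromM = M_prev - open1
        fromX = X_prev - ext
        X_row = np.maximum(fromM, fromX)
        ptrX[i] = (fromM < fromX).astype(np.int8)
        X_row[0] = -open1 - (i - 1) * ext
        ptrX[i, 0] = 1

        # Y: gap in a (horizontal), within-row recurrence solved by
        # a running maximum of M_row[j-1] + j*ext
        Y_row = np.full(m + 1, NEG)
        if m:
            cand = M_row[:-1] - open1 + js * ext
            run = np.maximum.accumulate(cand)
            Y_row[1:] = run - js * ext
            ptrY[i, 1:] = (M_row[:-1] - open1 < Y_row[:-1] - ext).astype(np.int8)
        M_prev, X_prev, Y_prev = M_row, X_row, Y_row

    finals = (M_prev[m], X_prev[m], Y_prev[m])
    state = int(np.argmax(finals))
    score = float(finals[state])

    # traceback
    i, j = n, m
    ident = 0
    aligned = 0
    mism = 0
    col_a: list[str] = []
    col_b: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            prev = ptrM[i, j]
            same = ea[i - 1] == eb[j - 1] and (alphabet == "aa" or ea[i - 1] != 4)
            aligned += 1
            if same:
                ident += 1
            else:
                mism += 1
            if keep_alignment:
                col_a.append(a[i - 1])
                col_b.append(b[j - 1])
            i -= 1
            j -= 1
            state = int(prev)
        elif state == _X:
            prev = ptrX[i, j]
            if keep_alignment:
                col_a.append(a[i - 1])
                col_b.append("-")
            i -= 1
            state = _X if prev else _M
        else:
            prev = ptrY[i, j]
            if keep_alignment:
                col_a.append("-")
                col_b.append(b[j - 1])
            j -= 1
            state = _Y if prev else _M

    identity = ident / aligned if aligned else 0.0
    return AlignmentIdentity(
        identity=identity,
        mismatches=mism,
        aligned_positions=aligned,
        score=score,
        aligned_a="".join(reversed(col_a)) if keep_alignment else "",
        aligned_b="".join(reversed(col_b)) if keep_alignment else "",
    )


@dataclass
class IdentityMatrix:
    """Symmetric pairwise identity / mismatch-count matrix over named sequences.

    ``identity[i, j]`` is the p-distance identity, ``mismatches[i, j]`` the
    number of differing aligned-residue columns and ``aligned_positions``
    the pairwise-gap-deleted column count, all from the same alignments.
    """

    names: list[str]
    identity: np.ndarray
    mismatches: np.ndarray
    aligned_positions: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.identity, self.mismatches, self.aligned_positions):
            if arr.shape != (n, n):
                raise ValueError("matrix shape does not match names")
        if not np.allclose(self.identity, self.identity.T):
            raise ValueError("identity matrix is not symmetric")
        if not np.allclose(np.diag(self.identity), 1.0):
            raise ValueError("identity diagonal must be 1")

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[tuple[str, str]] | dict[str, str],
        alphabet: str = "nt",
    ) -> "IdentityMatrix":
        """All-vs-all global alignment of ``(name, sequence)`` pairs."""
        items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names")
        n = len(items)
        ident = np.eye(n)
        mism = np.zeros((n, n), dtype=np.int64)
        alnd = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            alnd[i, i] = len(items[i][1])
        for i in range(n):
            for j in range(i + 1, n):
                r = global_align_identity(items[i][1], items[j][1], alphabet)
                ident[i, j] = ident[j, i] = r.identity
                mism[i, j] = mism[j, i] = r.mismatches
                alnd[i, j] = alnd[j, i] = r.aligned_positions
        return cls(names, ident, mism, alnd)

    def pair(self, a: str, b: str) -> tuple[float, int]:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.identity[i, j]), int(self.mismatches[i, j])

    def render_table(self) -> str:
        """Combined table: upper triangle identity (2 decimals), lower
        triangle integer mismatch counts, as in amplicon screening tables."""
        n = len(self.names)
        width = max([len(x) for x in self.names] + [6])
        rows = ["\t".join([" " * width] + [f"{x:>{width}}" for x in self.names])]
        for i in range(n):
            cells = [f"{self.names[i]:>{width}}"]
            for j in range(n):
                if i == j:
                    cells.append(f"{'':>{width}}")
                elif i < j:
                    cells.append(f"{self.identity[i, j]:>{width}.2f}")
                else:
                    cells.append(f"{int(self.mismatches[i, j]):>{width}d}")
            rows.append("\t".join(cells))
        return "\n".join(rows) + "\n"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.render_table())
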