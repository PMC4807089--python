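"""Alignment trimming, nucleotide/protein distances, neighbor-joining
trees and bootstrap support.

The tree machinery is a distance-based stand-in for maximum-likelihood
inference: Kimura 2-parameter (nucleotide) or p-distance (amino acid)
distances feed Saitou-Nei neighbor joining, with column-resampling
bootstrap support.  Topology, not likelihood, is the contract.

Alignment trimming follows the Gblocks parameter semantics (conserved /
flank occupancy thresholds, maximum run of contiguous nonconserved
positions, minimum block length, gap policy); bit-compatibility with the
Gblocks binary is not claimed.  A position counts as conserved when
strictly more than ``min_seqs_conserved`` sequences share its most
frequent residue, and as flank-grade when at least ``min_seqs_flank`` do.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class SaturationError(ValueError):
    """Distance formula undefined: too many differences for the model."""


# ---------------------------------------------------------------------------
# Gblocks-style trimming


@dataclass
class TrimConfig:
    min_seqs_conserved: int
    min_seqs_flank: int
    max_contig_nonconserved: int = 20
    min_block_len: int = 4
    gap_policy: str = "all"   # none | half | all

    def __post_init__(self) -> None:
        if self.min_seqs_flank < self.min_seqs_conserved:
            raise ValueError("min_seqs_flank must be >= min_seqs_conserved")
        for v in (self.min_seqs_conserved, self.min_seqs_flank,
                  self.max_contig_nonconserved, self.min_block_len):
            if v <= 0:
                raise ValueError("trim parameters must be positive")
        if self.gap_policy not in ("none", "half", "all"):
            raise ValueError("gap_policy must be none, half or all")


_NONCONS, _CONS, _FLANK = 0, 1, 2


def _column_status(col: Sequence[str], cfg: TrimConfig) -> int:
    n = len(col)
    gaps = sum(c == "-" for c in col)
    if cfg.gap_policy == "none" and gaps > 0:
        return _NONCONS
    if cfg.gap_policy == "half" and gaps * 2 > n:
        return _NONCONS
    counts: dict[str, int] = {}
    for c in col:
        if c != "-":
            counts[c] = counts.get(c, 0) + 1
    top = max(counts.values()) if counts else 0
    if top >= cfg.min_seqs_flank:
        return _FLANK
    if top > cfg.min_seqs_conserved:
        return _CONS
    return _NONCONS


def trim_blocks(
    msa: Sequence[tuple[str, str]],
    cfg: TrimConfig,
) -> tuple[list[tuple[str, str]], list[int]]:
    """Trim noninformative alignment columns, Gblocks-style.

    Returns the trimmed alignment and the (strictly increasing) indices of
    kept columns.  Stretches of more than ``max_contig_nonconserved``
    consecutive nonconserved columns are rejected; the surviving segments
    are trimmed inward until they begin and end with flank-grade columns,
    then segments shorter than ``min_block_len`` are dropped.
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0][1])
    if any(len(s) != L for _, s in msa):
        raise ValueError("ragged alignment")
    status = [
        _column_status([s[j] for _, s in msa], cfg) for j in range(L)
    ]

    # 1. reject long nonconserved runs
    rejected = np.zeros(L, dtype=bool)
    j = 0
    while j < L:
        if status[j] == _NONCONS:
            k = j
            while k < L and status[k] == _NONCONS:
                k += 1
            if k - j > cfg.max_contig_nonconserved:
                rejected[j:k] = True
            j = k
        else:
            j += 1

    # 2. split into segments, trim to flank-grade ends, apply min length
    kept: list[int] = []
    j = 0
    while j < L:
        if rejected[j]:
            j += 1
            continue
        k = j
        while k < L and not rejected[k]:
            k += 1
        seg = list(range(j, k))
        while seg and status[seg[0]] != _FLANK:
            seg.pop(0)
        while seg and status[seg[-1]] != _FLANK:
            seg.pop()
        if len(seg) >= cfg.min_block_len:
            kept.extend(seg)
        j = k
    if not kept:
        warnings.warn("no alignment blocks survive trimming")
    trimmed = [(name, "".join(s[c] for c in kept)) for name, s in msa]
    return trimmed, kept


# ---------------------------------------------------------------------------
# distances

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID_NT = frozenset("ACGT")


def _paired_sites(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return [
        (x, y)
        for x, y in zip(a.upper().replace("U", "T"), b.upper().replace("U", "T"))
        if x in _VALID_NT and y in _VALID_NT
    ]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing residues over shared non-gap columns."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [
        (x, y) for x, y in zip(a.upper(), b.upper())
        if x not in "-.?" and y not in "-.?"
    ]
    if not pairs:
        raise ValueError("no shared residue columns")
    return sum(x != y for x, y in pairs) / len(pairs)


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance of an aligned nucleotide pair:
    ``d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` with P, Q the transition
    and transversion fractions over pairwise-complete sites."""
    pairs = _paired_sites(a, b)
    if not pairs:
        raise ValueError("no comparable sites")
    n = len(pairs)
    transitions = transversions = 0
    for x, y in pairs:
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    P, Q = transitions / n, transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined at P={P:.3f}, Q={Q:.3f} (saturated divergence)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")


def alignment_distance_matrix(
    aln: Sequence[tuple[str, str]], model: str = "k2p"
) -> DistanceMatrix:
    """Pairwise distances over an alignment; ``model`` is ``"k2p"`` or
    ``"p"``."""
    fn = {"k2p": k2p_distance, "p": p_distance}[model]
    names = [n for n, _ in aln]
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(aln[i][1], aln[j][1])
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{child._nwk(ws)}:{length:.6g}" for child, length in self.children
        )
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree represented
    with a trifurcating root.  Negative branch lengths are clamped to
    zero; Q-matrix ties are broken by the lexicographically smallest
    taxon-label pair (internal clusters are labelled by their smallest
    leaf)."""
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in dm.names]
    labels: list[str] = list(dm.names)
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            dv = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = max(dv, 0.0)
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    order = sorted([(labels[i], i, li), (labels[j], j, lj), (labels[k], k, lk)])
    return TreeNode(
        children=[(nodes[idx], max(length, 0.0)) for _, idx, length in order]
    )


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions of an unrooted tree, each encoded as the
    leaf set on the side not containing the alphabetically first taxon."""
    all_leaves = sorted(tree.leaves())
    ref = all_leaves[0]
    total = set(all_leaves)
    splits: set[frozenset[str]] = set()

    def visit(node: TreeNode) -> set[str]:
        if not node.children:
            return {node.name}  # type: ignore[arg-type]
        below: set[str] = set()
        for child, _ in node.children:
            below |= visit(child)
        if node is not tree and 1 < len(below) < len(total) - 1:
            side = below if ref not in below else total - below
            splits.add(frozenset(side))
        return below

    visit(tree)
    return splits


def _annotate_supports(tree: TreeNode, freqs: dict[frozenset[str], float]) -> None:
    all_leaves = set(tree.leaves())
    ref = sorted(all_leaves)[0]

    def visit(node: TreeNode) -> set[str]:
        if not node.children:
            return {node.name}  # type: ignore[arg-type]
        below: set[str] = set()
        for child, _ in node.children:
            below |= visit(child)
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = round(100.0 * freqs.get(frozenset(side), 0.0))
        return below

    visit(tree)


def bootstrap_support(
    aln: Sequence[tuple[str, str]],
    n_reps: int = 100,
    seed: int = 0,
    model: str = "k2p",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports (percent of
    column-resampled replicates containing each bipartition).  With
    ``n_reps=0`` the tree carries no support annotations.  Replicates
    whose resampled distances saturate are skipped."""
    L = len(aln[0][1])
    if L < 1:
        raise ValueError("alignment has no columns")
    full = nj_tree(alignment_distance_matrix(aln, model))
    if n_reps <= 0:
        return full
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = [(name, "".join(seq[c] for c in cols)) for name, seq in aln]
        try:
            t = nj_tree(alignment_distance_matrix(rep, model))
        except (SaturationError, ValueError):
            continue
        n_ok += 1
        for split in tree_splits(t):
            counts[split] = counts.get(split, 0) + 1
    denom = max(n_ok, 1)
    _annotate_supports(full, {s: c / denom for s, c in counts.items()})
    return full
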