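"""Phylotype dereplication, species delimitation and nomenclature.

Partial genomes sharing more than 70% nucleotide identity in the RdRp or
maturation gene belong to one phylotype (single-linkage closure of that
pairwise relation; strict inequality).  The longest member represents the
phylotype.  Species are delimited on an RdRp amino-acid identity matrix
at a chosen cutoff (non-strict ``>=``), swept over several cutoffs to
show how the species count depends on the threshold.  Names follow the
one-letter source / two-letter niche / three-digit convention
(``AVE000``, ``EMS013``...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .identity import IdentityMatrix, global_align_identity

PHYLOTYPE_GENES = ("rdrp", "maturation")


@dataclass
class GeneSet:
    """One partial genome presented for dereplication: its id, its total
    length and the nucleotide sequences of the genes used for clustering
    (roles ``rdrp`` / ``maturation``; absent genes omitted)."""

    genome_id: str
    length: int
    genes: dict[str, str]


@dataclass
class Phylotype:
    label: str
    members: list[str]
    representative: str
    niche: str = ""


def cluster_phylotypes(
    genomes: Sequence[GeneSet],
    gene: str = "either",
    threshold: float = 0.70,
    min_aligned: int = 0,
) -> list[Phylotype]:
    """Single-linkage phylotype clustering at strict ``identity > threshold``.

    ``gene`` selects which gene(s) define the pairwise relation:
    ``"rdrp"``, ``"maturation"`` or ``"either"`` (linked if either gene
    exceeds the threshold).  ``min_aligned`` discards gene comparisons
    with fewer aligned residue columns - identity "across the gene" is
    not meaningfully established by a short motif-spanning fragment.
    Genomes lacking every selected gene are excluded with a warning.
    Representatives are the longest members, ties broken by
    lexicographically smallest id.
    """
    roles = PHYLOTYPE_GENES if gene == "either" else (gene,)
    usable = []
    for g in genomes:
        if any(r in g.genes for r in roles):
            usable.append(g)
        else:
            warnings.warn(f"genome {g.genome_id!r} lacks {'/'.join(roles)}; excluded")
    graph = nx.Graph()
    graph.add_nodes_from(g.genome_id for g in usable)
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            for role in roles:
                if role in a.genes and role in b.genes:
                    r = global_align_identity(a.genes[role], b.genes[role], "nt")
                    if r.aligned_positions >= min_aligned and r.identity > threshold:
                        graph.add_edge(a.genome_id, b.genome_id)
                        break
    lengths = {g.genome_id: g.length for g in usable}
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    out = []
    for k, comp in enumerate(comps):
        members = sorted(comp)
        rep = min(members, key=lambda m: (-lengths[m], m))
        out.append(Phylotype(label=f"phylotype{k:03d}", members=members,
                             representative=rep))
    return out


def count_species(matrix: IdentityMatrix, cutoff: float) -> int:
    """Single-linkage component count with edges at ``identity >= cutoff``
    (cutoff in percent, non-strict)."""
    graph = nx.Graph()
    graph.add_nodes_from(matrix.names)
    n = len(matrix.names)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.identity[i, j] * 100.0 >= cutoff:
                graph.add_edge(matrix.names[i], matrix.names[j])
    return nx.number_connected_components(graph)


@dataclass
class SpeciesTable:
    cutoffs: list[float]
    counts: dict[float, int]

    def __post_init__(self) -> None:
        ordered = sorted(self.cutoffs)
        vals = [self.counts[c] for c in ordered]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("species counts must be non-decreasing in cutoff")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("amino_acid_identity_cutoff\tn_species\n")
            for c in self.cutoffs:
                fh.write(f"{c:g}\t{self.counts[c]}\n")


def species_table(
    matrix: IdentityMatrix, cutoffs: Sequence[float] = (70, 60, 50, 40)
) -> SpeciesTable:
    """Species counts across amino-acid identity cutoffs (percent)."""
    counts = {float(c): count_species(matrix, c) for c in cutoffs}
    return SpeciesTable(cutoffs=[float(c) for c in cutoffs], counts=counts)


def amplicon_matrix(
    amplicons: Sequence[tuple[str, str]] | Mapping[str, str],
    aligned: bool = False,
) -> IdentityMatrix:
    """Pairwise identity / mismatch matrix over amplicon sequences.

    For pre-aligned input (equal lengths, gaps as ``-``), columns where
    either sequence gaps are deleted pairwise; otherwise each pair is
    globally aligned.  ``render_table()`` on the result prints the
    combined format: identities (2 decimals) above the diagonal, mismatch
    counts below.
    """
    items = list(amplicons.items()) if isinstance(amplicons, Mapping) else list(amplicons)
    if len(items) < 2:
        raise ValueError("need at least two amplicons")
    if not aligned:
        return IdentityMatrix.from_sequences(items, alphabet="nt")
    names = [n for n, _ in items]
    n = len(items)
    ident = np.eye(n)
    mism = np.zeros((n, n), dtype=np.int64)
    alnd = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        alnd[i, i] = sum(c != "-" for c in items[i][1])
    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i][1].upper(), items[j][1].upper()
            if len(a) != len(b):
                raise ValueError("aligned amplicons must have equal lengths")
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            same = sum(x == y for x, y in pairs)
            ident[i, j] = ident[j, i] = same / len(pairs) if pairs else 0.0
            mism[i, j] = mism[j, i] = len(pairs) - same
            alnd[i, j] = alnd[j, i] = len(pairs)
    return IdentityMatrix(names, ident, mism, alnd)


NICHE_CODES = ("IN", "VE", "SE", "SO", "MS", "MM", "OC")


def assign_name(source: str, niche: str, index: int) -> str:
    """Phylotype name: source letter (A=animal, E=environmental) +
    two-letter niche code + zero-padded three-digit index."""
    letters = {"animal": "A", "environmental": "E"}
    if source not in letters:
        raise ValueError(f"source must be 'animal' or 'environmental', got {source!r}")
    if niche not in NICHE_CODES:
        raise ValueError(f"unknown niche {niche!r}; expected one of {NICHE_CODES}")
    if not (0 <= index <= 999):
        raise ValueError("index must be in [0, 999]")
    return f"{letters[source]}{niche}{index:03d}"


def write_phylotypes_tsv(
    phylotypes: Sequence[Phylotype], lengths: Mapping[str, int], path
) -> None:
    with open(path, "w") as fh:
        fh.write("label\trepresentative\trepresentative_length\tn_members\tmembers\n")
        for pt in phylotypes:
            fh.write(
                f"{pt.label}\t{pt.representative}\t{lengths[pt.representative]}\t"
                f"{len(pt.members)}\t{','.join(pt.members)}\n"
            )
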