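"""Trimming, distances, neighbor joining, bootstrap."""

import math

import dendropy
import numpy as np
import pytest

from rnaphage.phylo import (
    DistanceMatrix,
    SaturationError,
    TrimConfig,
    TreeNode,
    alignment_distance_matrix,
    bootstrap_support,
    k2p_distance,
    nj_tree,
    p_distance,
    tree_splits,
    trim_blocks,
)

from conftest import random_seq


def aln_of(rows):
    return [(f"t{i}", s) for i, s in enumerate(rows)]


class TestTrimBlocks:
    CFG = TrimConfig(min_seqs_conserved=3, min_seqs_flank=5,
                     max_contig_nonconserved=4, min_block_len=4)

    def test_fully_conserved_alignment_kept(self):
        msa = aln_of(["ACGTACGTAC"] * 6)
        trimmed, kept = trim_blocks(msa, self.CFG)
        assert kept == list(range(10))
        assert trimmed[0][1] == "ACGTACGTAC"

    def test_long_divergent_insert_removed(self):
        conserved = "ACGTACGTACGT"
        rows = []
        for i in range(6):
            # 8 columns where no residue is shared by more than 2 sequences
            insert = "".join("ACGT"[(i + j) % 4] for j in range(8))
            rows.append(conserved + insert + conserved)
        trimmed, kept = trim_blocks(aln_of(rows), self.CFG)
        assert kept == list(range(12)) + list(range(20, 32))

    def test_block_shorter_than_minimum_dropped(self):
        # only 3 conserved columns amid noise
        rows = []
        rng = np.random.default_rng(4)
        for _ in range(6):
            rows.append(random_seq(rng, 6) + "ACG" + random_seq(rng, 6))
        with pytest.warns(UserWarning):
            trimmed, kept = trim_blocks(aln_of(rows), self.CFG)
        assert kept == []
        assert all(s == "" for _, s in trimmed)

    def test_kept_columns_strictly_increasing(self, rng):
        rows = [random_seq(rng, 40) for _ in range(3)] + ["A" * 40] * 5
        _, kept = trim_blocks(aln_of(rows), self.CFG)
        assert kept == sorted(set(kept))

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            trim_blocks([("a", "ACGT"), ("b", "ACG")], self.CFG)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrimConfig(min_seqs_conserved=5, min_seqs_flank=3)


class TestDistances:
    def test_identical_pair_is_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_formula_on_counted_changes(self):
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85  # 10 transitions, 5 transversions
        d = k2p_distance(a, b)
        expect = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert d == pytest.approx(expect, abs=1e-4)
        assert round(d, 4) == 0.1702

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 50, "G" * 50)

    def test_gapped_sites_excluded_pairwise(self):
        d = k2p_distance("ACGT--AC", "ACGTAC-C")
        assert d == 0.0

    def test_k2p_at_least_p_distance_behaviour(self, rng):
        for _ in range(20):
            a = random_seq(rng, 200)
            b = list(a)
            for p in rng.choice(200, size=20, replace=False):
                b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
            b = "".join(b)
            assert k2p_distance(a, b) >= p_distance(a, b) - 1e-12
            assert k2p_distance(a, a) == 0.0


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths; returns
    (TreeNode, distance matrix) where distances are path lengths."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = {n: TreeNode(name=n) for n in names}
    dist = {n: {n: 0.0} for n in names}
    members = {n: [n] for n in names}
    alive = list(names)
    while len(alive) > 2:
        i, j = sorted(rng.choice(len(alive), size=2, replace=False))
        a, b = alive[i], alive[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        new = f"({a},{b})"
        nodes[new] = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        members[new] = members[a] + members[b]
        for x in members[a]:
            dist[x][new] = dist[x][a] + la
        for x in members[b]:
            dist[x][new] = dist[x][b] + lb
        for x in members[a]:
            for y in members[b]:
                d = dist[x][a] + la + lb + dist[y][b]
                dist[x][y] = dist[y][x] = d
        alive = [x for x in alive if x not in (a, b)] + [new]
    a, b = alive
    l = rng.uniform(0.2, 1.0)
    root = TreeNode(children=[(nodes[a], l / 2), (nodes[b], l / 2)])
    for x in members[a]:
        for y in members[b]:
            d = dist[x][a] + l + dist[y][b]
            dist[x][y] = dist[y][x] = d
    mat = np.array([[dist[x][y] for y in names] for x in names])
    return root, DistanceMatrix(names, mat)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["X", "Y", "Z"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = nj_tree(dm)
        lengths = {child.name: l for child, l in t.children}
        assert lengths == {"X": pytest.approx(1.0), "Y": pytest.approx(2.0),
                           "Z": pytest.approx(3.0)}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1))
        d = np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float)
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree_splits(t) == {frozenset({"C", "D"})}
        newick = t.newick()
        dt = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in dt.taxon_namespace}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_additive_topology_recovery_property(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            true_tree, dm = random_additive_tree(rng, 6)
            got = nj_tree(dm)
            assert tree_splits(got) == tree_splits(true_tree)

    def test_negative_branches_clamped(self):
        d = np.array(
            [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.02], [0.5, 0.5, 0.02, 0]]
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), d))

        def all_lengths(node):
            for child, l in node.children:
                yield l
                yield from all_lengths(child)

        assert all(l >= 0 for l in all_lengths(t))


class TestBootstrap:
    def _two_clade_alignment(self, rng, n_cols=500):
        base = random_seq(rng, n_cols)
        other = list(base)
        for p in rng.choice(n_cols, size=n_cols // 3, replace=False):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        other = "".join(other)

        def vary(s, k):
            out = list(s)
            for p in rng.choice(len(s), size=k, replace=False):
                out[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[out[p]]
            return "".join(out)

        return [("a1", vary(base, 5)), ("a2", vary(base, 5)),
                ("b1", vary(other, 5)), ("b2", vary(other, 5))]

    def test_planted_split_gets_high_support(self):
        rng = np.random.default_rng(5)
        aln = self._two_clade_alignment(rng)
        t = bootstrap_support(aln, n_reps=100, seed=3)
        splits = {}

        def walk(node):
            for child, _ in node.children:
                if child.children:
                    splits[frozenset(child.leaves())] = child.support
                walk(child)

        walk(t)
        (support,) = [v for k, v in splits.items() if k in
                      ({"a1", "a2"}, {"b1", "b2"}) or len(k) == 2]
        assert support >= 95

    def test_zero_replicates_leave_no_annotations(self):
        rng = np.random.default_rng(6)
        aln = self._two_clade_alignment(rng)
        t = bootstrap_support(aln, n_reps=0, seed=1)

        def supports(node):
            yield node.support
            for child, _ in node.children:
                yield from supports(child)

        assert all(s is None for s in supports(t))

    def test_same_seed_same_supports(self):
        rng = np.random.default_rng(7)
        aln = self._two_clade_alignment(rng)
        t1 = bootstrap_support(aln, n_reps=30, seed=11)
        t2 = bootstrap_support(aln, n_reps=30, seed=11)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)
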