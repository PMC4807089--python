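"""Phylotype clustering, species delimitation, amplicon tables, naming."""

import numpy as np
import pytest

from rnaphage.dereplication import (
    GeneSet,
    amplicon_matrix,
    assign_name,
    cluster_phylotypes,
    count_species,
    species_table,
)
from rnaphage.identity import IdentityMatrix

from conftest import random_seq
from oracles import components_brute


def identity_matrix_from_blocks(blocks, within, between):
    """Synthetic IdentityMatrix: ``blocks`` lists of names; pairs inside a
    block get ``within`` identity, across blocks ``between``."""
    names = [n for b in blocks for n in b]
    of = {n: k for k, b in enumerate(blocks) for n in b}
    n = len(names)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = within if of[names[i]] == of[names[j]] else between
            ident[i, j] = ident[j, i] = v
    aligned = np.full((n, n), 1000, dtype=np.int64)
    mism = np.rint((1 - ident) * aligned).astype(np.int64)
    np.fill_diagonal(mism, 0)
    return IdentityMatrix(names, ident, mism, aligned)


def exact_identity_pair(rng, length=300, identity=0.70):
    """Two equal-length sequences at exactly the requested identity, with
    substitutions spread out so the global alignment stays gap-free."""
    a = random_seq(rng, length)
    k = round((1 - identity) * length)
    b = list(a)
    step = length // k
    for i in range(k):
        p = i * step
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    return a, "".join(b)


class TestClusterPhylotypes:
    def test_variants_join_their_seed_genome(self, small_community):
        c = small_community
        gene_sets = [
            GeneSet(g.id, len(g.sequence),
                    {"rdrp": g.gene("rdrp"), "maturation": g.gene("maturation")})
            for g in c.genomes
        ]
        pts = cluster_phylotypes(gene_sets, gene="either", threshold=0.70)
        assert len(pts) == 3
        for pt in pts:
            truth = {m.split("_")[0] for m in pt.members}
            assert len(truth) == 1
            assert pt.representative.endswith("_g00")  # longest planted member

    def test_exact_threshold_does_not_link(self, rng):
        a, b = exact_identity_pair(rng, 300, 0.70)
        gs = [GeneSet("x", 300, {"rdrp": a}), GeneSet("y", 300, {"rdrp": b})]
        assert len(cluster_phylotypes(gs, gene="rdrp", threshold=0.70)) == 2

    def test_just_above_threshold_links(self, rng):
        a, b = exact_identity_pair(rng, 300, 0.75)
        gs = [GeneSet("x", 300, {"rdrp": a}), GeneSet("y", 300, {"rdrp": b})]
        assert len(cluster_phylotypes(gs, gene="rdrp", threshold=0.70)) == 1

    def test_either_gene_links(self, rng):
        a, b = exact_identity_pair(rng, 300, 0.90)
        far_a, far_b = random_seq(rng, 300), random_seq(rng, 300)
        gs = [
            GeneSet("x", 300, {"rdrp": far_a, "maturation": a}),
            GeneSet("y", 300, {"rdrp": far_b, "maturation": b}),
        ]
        assert len(cluster_phylotypes(gs, gene="either")) == 1
        assert len(cluster_phylotypes(gs, gene="rdrp")) == 2

    def test_genome_without_marker_genes_excluded(self):
        gs = [GeneSet("x", 100, {"rdrp": "ATGAAATTTGGGCCC"}), GeneSet("y", 100, {})]
        with pytest.warns(UserWarning):
            pts = cluster_phylotypes(gs)
        assert {m for pt in pts for m in pt.members} == {"x"}

    def test_representative_tie_broken_by_id(self):
        seq = "ATGGCTGCAGCTGCAGCTGCATAA" * 10
        gs = [GeneSet("b", 500, {"rdrp": seq}), GeneSet("a", 500, {"rdrp": seq})]
        pts = cluster_phylotypes(gs)
        assert pts[0].representative == "a"


class TestCountSpecies:
    def test_identical_triplet(self):
        m = identity_matrix_from_blocks([["a", "b", "c"]], 1.0, 0.0)
        assert count_species(m, 60) == 1

    def test_planted_blocks_match_component_oracle(self):
        m = identity_matrix_from_blocks(
            [["a1", "a2"], ["b1", "b2"], ["c1", "c2"], ["d1", "d2"]], 0.8, 0.3
        )
        got = count_species(m, 60)
        idx = {n: i for i, n in enumerate(m.names)}
        expect = components_brute(
            m.names, lambda a, b: m.identity[idx[a], idx[b]] * 100 >= 60
        )
        assert got == expect == 4

    def test_cutoff_is_inclusive(self):
        m = identity_matrix_from_blocks([["a"], ["b"]], 1.0, 0.60)
        assert count_species(m, 60) == 1   # >= 60 merges
        assert count_species(m, 60.01) == 2

    def test_extreme_cutoffs(self):
        m = identity_matrix_from_blocks([["a", "b"], ["c", "d"]], 0.9, 0.4)
        assert count_species(m, 0) == 1
        assert count_species(m, 101) == 4


class TestSpeciesTable:
    def test_singletons(self):
        m = identity_matrix_from_blocks([["only"]], 1.0, 0.0)
        t = species_table(m)
        assert all(v == 1 for v in t.counts.values())

    def test_hierarchical_blocks(self):
        blocks = [[f"s{g}{i}" for i in range(3)] for g in range(9)]
        supers = [blocks[0] + blocks[1] + blocks[2],
                  blocks[3] + blocks[4] + blocks[5],
                  blocks[6] + blocks[7] + blocks[8]]
        names = [n for b in blocks for n in b]
        of_block = {n: k for k, b in enumerate(blocks) for n in b}
        of_super = {n: k for k, s in enumerate(supers) for n in s}
        n = len(names)
        ident = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if of_block[names[i]] == of_block[names[j]]:
                    v = 0.75
                elif of_super[names[i]] == of_super[names[j]]:
                    v = 0.55
                else:
                    v = 0.20
                ident[i, j] = ident[j, i] = v
        aligned = np.full((n, n), 1000, dtype=np.int64)
        mism = np.rint((1 - ident) * aligned).astype(np.int64)
        np.fill_diagonal(mism, 0)
        m = IdentityMatrix(names, ident, mism, aligned)
        t = species_table(m, cutoffs=(80, 60, 50, 30))
        assert [t.counts[c] for c in (80, 60, 50, 30)] == [27, 9, 3, 3]

    def test_monotone_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 10))
            raw = rng.random((n, n))
            ident = (raw + raw.T) / 2
            np.fill_diagonal(ident, 1.0)
            aligned = np.full((n, n), 100, dtype=np.int64)
            mism = np.rint((1 - ident) * aligned).astype(np.int64)
            np.fill_diagonal(mism, 0)
            m = IdentityMatrix([f"s{i}" for i in range(n)], ident, mism, aligned)
            t = species_table(m, cutoffs=(90, 70, 50, 30, 10))
            vals = [t.counts[c] for c in sorted(t.counts)]
            assert vals == sorted(vals)


class TestAmpliconMatrix:
    def test_identical_pair(self):
        m = amplicon_matrix([("a", "ACGT" * 50), ("b", "ACGT" * 50)])
        assert m.pair("a", "b") == (1.0, 0)

    def test_planted_substitutions(self, rng):
        a = random_seq(rng, 500)
        b = list(a)
        for p in (10, 110, 210, 310, 410):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        m = amplicon_matrix([("x", a), ("y", "".join(b))])
        ident, mism = m.pair("x", "y")
        assert mism == 5 and ident == pytest.approx(0.99)

    def test_rendered_layout_matches_screening_table_format(self, rng):
        a = random_seq(rng, 200)
        m = amplicon_matrix([("s1", a), ("s2", a), ("s3", random_seq(rng, 200))])
        text = m.render_table()
        lines = text.splitlines()
        assert lines[0].split("\t")[1:] == [f"{n:>6}" for n in ("s1", "s2", "s3")]
        # identity cells carry two decimals, mismatch cells are integers
        assert "1.00" in lines[1]
        assert lines[2].split("\t")[1].strip().isdigit()

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            amplicon_matrix([("a", "ACGT")])


class TestAssignName:
    @pytest.mark.parametrize(
        "source,niche,index,expect",
        [
            ("animal", "VE", 0, "AVE000"),
            ("environmental", "MS", 13, "EMS013"),
            ("environmental", "OC", 7, "EOC007"),
        ],
    )
    def test_naming_convention(self, source, niche, index, expect):
        assert assign_name(source, niche, index) == expect

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assign_name("animal", "VE", 1000)
        with pytest.raises(ValueError):
            assign_name("plant", "VE", 1)
        with pytest.raises(ValueError):
            assign_name("animal", "ZZ", 1)
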