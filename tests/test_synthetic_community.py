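"""Generator tests: templates, planted identities, read simulation."""

import numpy as np
import pytest

from rnaphage.identity import global_align_identity
from rnaphage.synthetic_community import (
    START_CODONS,
    STOP_CODONS,
    GenomeTemplate,
    OrfSpec,
    SyntheticCommunitySpec,
    TemplateError,
    default_template,
    evolve_population,
    make_community,
    overlapping_orf_template,
    revcomp,
    shotgun_reads,
    simulate_genome,
)

from conftest import compact_template


class TestTemplates:
    def test_orf_grammar_holds_on_realized_genomes(self):
        for template in (default_template(), overlapping_orf_template(), compact_template()):
            seq, feats = simulate_genome(template, seed=3)
            assert len(seq) == template.length_nt
            for f in feats:
                assert seq[f.start : f.start + 3] in START_CODONS
                assert seq[f.end - 3 : f.end] in STOP_CODONS
                coding = seq[f.start : f.end - 3]
                for p in range(3, len(coding), 3):
                    assert coding[p : p + 3] not in STOP_CODONS
                assert "*" not in f.protein

    def test_declared_overlap_matches_coordinates(self):
        t = overlapping_orf_template(overlap_nt=259)
        ((pair, declared),) = t.declared_overlaps.items()
        novel = t._orf("novel")
        mat = t._orf("maturation")
        assert declared == min(novel.end, mat.end) - max(novel.start, mat.start) == 259

    def test_same_seed_reproduces_sequence(self):
        a, _ = simulate_genome(default_template(), seed=11)
        b, _ = simulate_genome(default_template(), seed=11)
        assert a == b

    def test_invalid_templates_rejected(self):
        with pytest.raises(ValueError):
            GenomeTemplate("bad", 100, [OrfSpec("rdrp", 0, 101)])
        with pytest.raises(ValueError):
            GenomeTemplate("bad", 100, [OrfSpec("rdrp", 0, 32)])  # not codon-sized
        with pytest.raises(ValueError):
            GenomeTemplate(
                "bad", 1000,
                [OrfSpec("novel", 0, 300), OrfSpec("maturation", 150, 600)],
                declared_overlaps={("novel", "maturation"): 100},
            )

    def test_same_frame_overlap_is_unrealizable(self):
        # two ORFs in the same frame sharing an interval: the upstream stop
        # codon would have to sit inside the downstream ORF
        t = GenomeTemplate(
            "clash", 2000,
            [OrfSpec("novel", 0, 600), OrfSpec("novel2", 300, 900)],
        )
        with pytest.raises(TemplateError):
            simulate_genome(t, seed=1)


class TestEvolvePopulation:
    def test_identity_one_gives_copies(self):
        anc = "ACGT" * 100
        assert evolve_population(anc, 1.0, 3, seed=1) == [anc] * 3

    @pytest.mark.parametrize("target", [0.90, 0.50])
    def test_planted_identity_matches_substitution_count(self, rng, target):
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        for v in evolve_population(anc, target, 5, seed=7):
            assert len(v) == len(anc)
            planted = sum(a != b for a, b in zip(anc, v)) / len(anc)
            assert abs((1 - planted) - target) <= 0.02
            # the dereplication aligner measures the same identity
            r = global_align_identity(anc, v, "nt")
            assert abs(r.identity - target) <= 0.02

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            evolve_population("ACGTACGT", 0.0, 1, seed=0)
        with pytest.raises(ValueError):
            evolve_population("ACGTACGT", 1.2, 1, seed=0)


class TestCommunity:
    def test_planted_within_and_between_identities(self, small_community):
        c = small_community
        by_pt = c.phylotypes()
        refs = {pt: c.genome(f"{pt}_g00") for pt in by_pt}
        for pt, members in by_pt.items():
            for gid in members:
                if gid == refs[pt].id:
                    continue
                g = c.genome(gid)
                ident = global_align_identity(
                    refs[pt].sequence, g.sequence, "nt"
                ).identity
                assert ident > 0.70
        for role in ("rdrp", "maturation"):
            pts = sorted(by_pt)
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    r = global_align_identity(
                        refs[pts[i]].gene(role), refs[pts[j]].gene(role), "nt"
                    )
                    assert r.identity < 0.70
                    assert abs(r.identity - 0.50) < 0.08

    def test_reference_is_longest_member(self, small_community):
        for pt, members in small_community.phylotypes().items():
            lengths = {m: len(small_community.genome(m).sequence) for m in members}
            assert max(lengths, key=lambda m: (lengths[m], m)) == f"{pt}_g00"

    def test_determinism(self):
        spec = SyntheticCommunitySpec(n_phylotypes=2, seed=9)
        a = make_community(spec, template=compact_template())
        b = make_community(spec, template=compact_template())
        assert [(g.id, g.sequence) for g in a.genomes] == [
            (g.id, g.sequence) for g in b.genomes
        ]


class TestShotgunReads:
    def _spec(self, **kw):
        base = dict(
            n_phylotypes=1, variants_per_phylotype=1, coverage=20.0,
            read_length_nt=200, substitution_error_rate=0.0,
            background_fraction=0.0, seed=5,
        )
        base.update(kw)
        return SyntheticCommunitySpec(**base)

    def test_poisson_read_count(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        spec = self._spec()
        reads, _ = shotgun_reads([("g", genome)], spec)
        lam = 20 * 4000 / 200  # 400
        assert abs(len(reads) - lam) <= 3 * np.sqrt(lam)

    def test_error_free_reads_are_substrings(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        reads, truth = shotgun_reads([("g", genome)], self._spec())
        for r in reads:
            assert r.sequence in genome or revcomp(r.sequence) in genome

    def test_background_fraction_and_labels(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        spec = self._spec(background_fraction=0.5)
        reads, truth = shotgun_reads([("g", genome)], spec)
        n_bg = sum(truth.reads[r.id]["phylotype"] == "background" for r in reads)
        n = len(reads)
        assert abs(n_bg - 0.5 * n) <= 3 * np.sqrt(n * 0.25)
        assert len(truth.reads) == n  # every read has exactly one record

    def test_strand_balance(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        reads, truth = shotgun_reads([("g", genome)], self._spec(coverage=40))
        minus = sum(truth.reads[r.id]["strand"] == "-" for r in reads)
        n = len(reads)
        assert abs(minus - n / 2) <= 3 * np.sqrt(n * 0.25)

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            shotgun_reads([("g", "ACGT" * 10)], self._spec(read_length_nt=200))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticCommunitySpec(within_phylotype_identity=0.65)
        with pytest.raises(ValueError):
            SyntheticCommunitySpec(between_phylotype_identity=0.75)
        with pytest.raises(ValueError):
            SyntheticCommunitySpec(coverage=0)
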