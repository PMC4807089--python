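# Methods

## Scope and model

The pipeline operationalizes sequence-based discovery of RNA
bacteriophages in RNA-inclusive metagenomes as a chain of decision
rules: translated homology triage (≥ 10 distinct reads at *E* < 10⁻⁴),
assembly, a > 750 nt contig filter, domain-based partial-genome
definition, phylotype dereplication at > 70 % nucleotide identity in
the RdRp or maturation gene, and species delimitation on RdRp
amino-acid identity at ≥ {70, 60, 50, 40} % cutoffs. Each rule keeps
the boundary semantics of its source: the triage and phylotype
thresholds are strict inequalities, the species cutoffs are
non-strict. The pipeline's phylotype count is anchored on unique RdRp
domains: clusters containing only maturation genes are reported but not
counted as additional phylotypes, since they may be disjoint fragments
of an already-counted genome.

## Pairwise identity

Identity everywhere is the p-distance convention: a Needleman–Wunsch
global alignment (Gotoh three-state affine DP), then
`identity = identical columns / columns where both sequences have a
residue`; gap columns are deleted pairwise and never count as
mismatches. Scoring: nucleotide match +2 / mismatch −3 with gap cost
10 + 4k for a gap of length k; amino acids use BLOSUM62 with gap cost
11 + k. The nucleotide gap costs are deliberately stiff relative to
the mismatch cost: with pairwise gap deletion, cheap gaps let the
global optimum convert mismatch-dense stretches into gap columns that
then vanish from the denominator, inflating the apparent identity of
highly divergent pairs by up to ~0.06 — exactly where the 0.70
phylotype threshold discriminates. With the stiff costs, alignments of
substitution-only diverged sequences stay gap-free while genuine end
truncations still align as terminal gaps.

Traceback tie-breaks are fixed (substitution preferred over a gap in
the second sequence, preferred over a gap in the first) so identity
values are reproducible; the vectorized DP is validated against a naive
table-filling oracle with identical scoring.

Phylotype links additionally require ≥ 450 aligned nucleotide columns
in the supporting gene (`min_gene_aligned`): a short motif-spanning
fragment does not establish identity "across the gene", and without
this guard conserved-motif fragments of unrelated phylotypes can exceed
70 % over a few hundred columns.

## Translated search

Reads are translated in six frames (standard code, stops as `*`,
ambiguous codons as `X`, trailing bases dropped). Seeding uses 3-mer
neighborhood words at BLOSUM62 score ≥ 13; words containing `X`/`*`
never seed. Seeded read/query pairs are scored by Smith–Waterman
(BLOSUM62, gap 11 + k; Biopython's C aligner) and converted to E-values
with the ungapped Karlin–Altschul parameters for BLOSUM62/11/1
(λ = 0.267, K = 0.041) applied to gapped scores, as BLAST does, with
database size = total translated letters over all six frames of all
reads. Agreement with NCBI BLAST numerics is not claimed; internal
ordering, thresholding, and completeness against an exhaustive
Smith–Waterman oracle (verified on 50-read × 5-query instances) are the
contract. "At least ten reads" counts distinct reads, not HSPs.

## Assembly

A deliberately small overlap-layout assembler replaces the original
heavy assembler, which is not the object under study. Any exact 20-mer
shared between two sequences (either strand) implies a candidate
suffix–prefix overlap; candidates are verified over the full overlap
and merged longest-overlap-first, ties broken by the lexicographically
smallest merged sequence, contigs reported on their canonical strand.
The pipeline default tolerance is 8 % mismatches in an overlap: contig
ends derive from single reads, so end-to-end joins carry roughly twice
the read error rate plus sampling noise, while the nearest wrong merge
(a 65 %-identical phylotype) is > 30 % divergent — the tolerance sits
far from both. `greedy_assemble`'s own default is exact overlaps.

## Domain models

Conserved-domain and structure services are replaced by packaged
position-specific scoring models. Because curated phage protein sets
cannot be bundled, the model set is **synthetic**: each domain family
(rdrp_ss, rdrp_ds, maturation, coat, ntpase, lysin, peptidoglycan
hydrolase) is generated deterministically from a fixed seed as a
consensus protein plus 20 diverged members, with short anchor windows —
the five palm motifs A–E for the RdRps — held nearly invariant while
the remainder drifts, the conservation structure real leviviral
proteins show. Scanning slides the model along a protein (overhangs
allowed, so truncated ORFs still match) and sums log-odds scores over
fully-covered anchor windows only; a hit requires 15 % of the consensus
anchor self-score (≈ 1.2 perfect motifs), and a motif counts as covered
at 50 % of its window self-score. These thresholds are calibrated so
that every family member passes on its own model while
composition-shuffled proteins fail in ≥ 95 of 100 shuffles; in
practice shuffled maxima sit > 25 score units below threshold.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
not a sequencing platform:

* **Genomes** realize a template (default: maturation–coat–RdRp on one
  strand, 3,810 nt, short UTRs; an AVE000-style variant adds a novel
  5′ ORF overlapping maturation by 259 nt). ORF payloads are the
  packaged domain consensus proteins; overlapping ORFs are reconciled
  by synonymous recoding, and a stop codon is placed immediately
  upstream of each ORF so ORF prediction recovers planted coordinates
  exactly.
* **Between-phylotype divergence** from a shared root preserves reading
  frames (species are functional genomes): start/stop codons are fixed
  and substitutions that would create in-frame stops are re-drawn.
  Anchor windows diverge at 0.4× the non-anchor rate — full
  conservation would make short motif fragments spuriously similar
  across phylotypes — and per-region rates are solved numerically so
  each gene's expected pairwise identity equals the configured target.
  Targets below the mutational floor (≈ 0.3 with anchors) saturate.
* **Within-phylotype variants** use uniform Jukes–Cantor-style
  substitution at a fixed count of distinct sites, so each variant's
  identity to the phylotype reference equals the target exactly;
  mutations may disrupt ORFs, as in real data. Variants are
  end-truncated within the UTRs only, making "longest member =
  reference" well defined while keeping genes intact.
* **Reads**: per-genome Poisson counts at the configured coverage,
  uniform positions, both strands (binomial ½), per-base substitution
  errors, plus random background reads labelled as such in the truth
  table.

Defaults are the study conditions exercised end-to-end: 12 phylotypes,
within-identity 0.90, between-identity 0.50, 200 nt reads, 20×
coverage, 1 % error, 20 % background. Read length and coverage are
fixtures (no distributions were specified for the original datasets).
What passing tests show: the decision rules recover planted structure
under substitution-only divergence with conserved motifs. What they do
not show: robustness to indels, chimeric reads, platform-specific error
profiles, amplification bias, or real protein evolution — none of which
the generator emulates.

## Phylogenetics

Maximum-likelihood inference is out of scope; neighbor joining
(Saitou–Nei) on Kimura 2-parameter distances (nucleotide,
`d = −½ ln((1 − 2P − Q)√(1 − 2Q))`, saturation raises an error) or
p-distances (amino acid) is the distance-based substitute, with
topology the contract — NJ provably recovers additive matrices, which
the tests exercise on random 6-taxon trees. NJ Q-matrix ties pick the
lexicographically smallest taxon pair; negative branch lengths clamp to
zero. Bootstrap resamples columns with replacement (explicit seed) and
reports bipartition frequencies on the full-data tree.

Alignment trimming follows the Gblocks parameter semantics: a column is
conserved when strictly more than `min_seqs_conserved` sequences share
its most frequent residue and flank-grade at ≥ `min_seqs_flank`; runs
of more than `max_contig_nonconserved` nonconserved columns are
rejected, surviving segments are trimmed inward to flank-grade ends and
dropped below `min_block_len`; `gap_policy=all` leaves gap columns
eligible. Bit-compatibility with the Gblocks binary is not claimed, and
the manual motif-preserving curation applied in the original analysis
is not reproducible and not emulated.

## Prevalence

A specimen is positive for a phylotype with ≥ 1 assigned read
(metagenomic) or an amplicon (RT-PCR); the two evidence kinds are kept
as separate matrices with an explicit union view, since RT-PCR detects
a superset of metagenomic positives. Time points are categorical
labels. Persistence counts animals positive at ≥ 1 and ≥ 2 distinct
time points. Geographic clustering is summarized by the conservative
criterion min(within-site identity) > max(between-site identity).

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
the end-to-end community is 12 × ~3.8 kb genomes (~5,600 reads); the
clustering grid uses a compact 2.1 kb two-gene template with 3–25
phylotypes; oracle comparisons use ≤ 60-residue pairs (alignment),
50 × 5 instances (translated search) and 1–5 kb contigs (ORFs). All
randomness flows from explicit integer seeds; identical spec + seed
yields byte-identical outputs, recorded as hashes in the run manifest.

## Known limitations

Substitution-only divergence means gap handling is exercised only by
end truncations; the assembler performs no consensus polishing, so
contigs inherit single-read errors (~1 %); the packaged domain models
are synthetic stand-ins and say nothing about sensitivity on real
proteins; species counts at cutoffs near the amino-acid identity floor
(~35 %) depend on alignment convention; and nomenclature assignment is
formatting only, with no registry semantics.
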