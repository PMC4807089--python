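"""Synthetic levivirus-like communities with known ground truth.

Generates phage genomes realizing a maturation-coat-RdRp layout (with
optional extra or overlapping ORFs), populations of phylotypes at
controlled pairwise nucleotide identities, and shotgun read sets with
substitution errors plus non-phage background reads.  Every emitted
sequence carries exactly one truth record, so downstream stages (triage,
assembly, annotation, dereplication) can be validated against planted
truth without any external data.

Divergence model
----------------
Within a phylotype, variants are produced by uniform (Jukes-Cantor-style)
substitutions at a fixed count of distinct positions, so each variant's
identity to the phylotype reference equals the requested target exactly
(up to rounding).  Between phylotypes, divergence from a shared root
preserves the nucleotides of the packaged domain anchor windows (the
conserved motifs real leviviral proteins keep while the rest of the gene
drifts) and compensates by raising the substitution rate at the remaining
sites so each gene region still realizes the configured pairwise
identity.  Targets below the anchored identity floor (~0.33 for random
sequences with conserved anchors) saturate at the floor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import motifs as _motifs

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_FOR_AA.setdefault(aa, tuple())
    CODONS_FOR_AA[aa] = CODONS_FOR_AA[aa] + (codon,)
AA_FOR_CODON = dict(_TABLE.forward_table)
for c in STOP_CODONS:
    AA_FOR_CODON[c] = "*"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class TemplateError(ValueError):
    """Raised when a genome template cannot be realized (e.g. overlapping
    ORFs whose frames force a stop codon into the partner ORF)."""


@dataclass(frozen=True)
class OrfSpec:
    role: str            # maturation | coat | rdrp | novel
    start: int           # 0-based, half-open, includes start and stop codon
    end: int
    strand: str = "+"


@dataclass
class GenomeTemplate:
    """Layout of one genome: ordered ORFs plus declared overlaps."""

    name: str
    length_nt: int
    orf_layout: list[OrfSpec]
    declared_overlaps: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError("length_nt must be positive")
        for orf in self.orf_layout:
            if not (0 <= orf.start < orf.end <= self.length_nt):
                raise ValueError(f"ORF {orf.role} outside [0, {self.length_nt})")
            if (orf.end - orf.start) % 3:
                raise ValueError(f"ORF {orf.role} length not divisible by 3")
            if orf.strand != "+":
                raise ValueError("only plus-strand ORFs are supported")
        for (ra, rb), declared in self.declared_overlaps.items():
            a = self._orf(ra)
            b = self._orf(rb)
            actual = max(0, min(a.end, b.end) - max(a.start, b.start))
            if actual != declared:
                raise ValueError(
                    f"declared overlap {ra}/{rb}={declared} but coordinates give {actual}"
                )

    def _orf(self, role: str) -> OrfSpec:
        for orf in self.orf_layout:
            if orf.role == role:
                return orf
        raise KeyError(role)


@dataclass(frozen=True)
class Feature:
    role: str
    start: int
    end: int
    strand: str
    protein: str


def default_template() -> GenomeTemplate:
    """Canonical levivirus-like layout: maturation, coat, RdRp on one
    strand, short UTRs, total 3,810 nt (within the 3.7-5.0 kb range)."""
    return GenomeTemplate(
        name="levivirus_like",
        length_nt=3810,
        orf_layout=[
            OrfSpec("maturation", 180, 1473),   # 430 aa + stop
            OrfSpec("coat", 1503, 1896),        # 130 aa + stop
            OrfSpec("rdrp", 1926, 3564),        # 545 aa + stop
        ],
    )


def overlapping_orf_template(overlap_nt: int = 259) -> GenomeTemplate:
    """AVE000-style layout: a novel 5' ORF partially overlapping the
    maturation gene, genome ~4.95 kb."""
    novel_len = 1200  # nt, divisible by 3
    mat_start = 180 + novel_len - overlap_nt
    # keep maturation in a different frame than the novel ORF
    if (mat_start - 180) % 3 == 0:
        mat_start += 1
        overlap_nt = 180 + novel_len - mat_start
    mat_end = mat_start + 1293
    coat_start = mat_end + 30
    coat_end = coat_start + 393
    rdrp_start = coat_end + 30
    rdrp_end = rdrp_start + 1638
    return GenomeTemplate(
        name="ave000_like",
        length_nt=rdrp_end + 240,
        orf_layout=[
            OrfSpec("novel", 180, 180 + novel_len),
            OrfSpec("maturation", mat_start, mat_end),
            OrfSpec("coat", coat_start, coat_end),
            OrfSpec("rdrp", rdrp_start, rdrp_end),
        ],
        declared_overlaps={("novel", "maturation"): 180 + novel_len - mat_start},
    )


_ROLE_TO_MODEL = {"maturation": "maturation", "coat": "coat", "rdrp": "rdrp_ss"}


def _protein_for_orf(orf: OrfSpec, rng: np.random.Generator) -> str:
    """Protein payload: packaged consensus for annotated roles (truncated or
    padded to the ORF's capacity), random protein for novel ORFs."""
    capacity = (orf.end - orf.start) // 3 - 1  # aa incl. leading M, excl. stop
    if orf.role in _ROLE_TO_MODEL:
        consensus = _motifs.domain_model(_ROLE_TO_MODEL[orf.role]).consensus
        prot = consensus[:capacity]
        if len(prot) < capacity:
            extra = rng.integers(0, 20, size=capacity - len(prot))
            prot = prot + "".join(_motifs.AA[i] for i in extra)
    else:
        idx = rng.integers(0, 20, size=capacity)
        prot = "".join(_motifs.AA[i] for i in idx)
    return "M" + prot[1:]


def _fill_codons(protein: str, rng: np.random.Generator) -> str:
    parts = ["ATG"]
    for aa in protein[1:]:
        choices = CODONS_FOR_AA[aa]
        parts.append(choices[rng.integers(0, len(choices))])
    parts.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    return "".join(parts)


def _orf_violations(seq: list[str], orf: OrfSpec) -> list[tuple[str, int]]:
    """(kind, nt_position) violations of the ORF grammar on the current
    sequence: missing start, internal stop, missing terminal stop."""
    out = []
    s, e = orf.start, orf.end
    if "".join(seq[s : s + 3]) not in START_CODONS:
        out.append(("start", s))
    for p in range(s + 3, e - 3, 3):
        if "".join(seq[p : p + 3]) in STOP_CODONS:
            out.append(("internal_stop", p))
    if "".join(seq[e - 3 : e]) not in STOP_CODONS:
        out.append(("stop", e - 3))
    return out


def simulate_genome(
    template: GenomeTemplate, seed: int
) -> tuple[str, list[Feature]]:
    """Realize a template as a concrete genome sequence.

    Each ORF begins with a start codon, ends with a stop codon and decodes
    without internal stops; overlapping ORFs are reconciled by synonymous
    recoding of the partner ORF (free recoding where the partner is a
    ``novel`` ORF).  Identical template + seed yields an identical genome.
    """
    rng = np.random.default_rng(seed)
    seq = list("".join(_BASES[i] for i in rng.integers(0, 4, size=template.length_nt)))
    orfs = sorted(template.orf_layout, key=lambda o: o.start)
    filled: list[OrfSpec] = []
    for orf in orfs:
        protein = _protein_for_orf(orf, rng)
        coding = _fill_codons(protein, rng)
        write_from = orf.start
        for prev in filled:
            if prev.start < orf.end and orf.start < prev.end:
                write_from = max(write_from, min(prev.end, orf.end))
        # keep previously written bases in the overlap; codon phase of the
        # straddling codon is completed from this ORF's coding sequence
        for k in range(write_from - orf.start, len(coding)):
            seq[orf.start + k] = coding[k]
        filled.append(orf)

    _repair_overlaps(seq, orfs, template, rng)

    # place an in-frame stop codon immediately upstream of each ORF (real
    # leviviral UTRs close the upstream frame) so that ORF prediction
    # recovers exactly the planted coordinates on non-overlapping layouts
    for orf in orfs:
        lo = orf.start - 3
        if lo >= 0 and not any(
            o is not orf and o.start < orf.start and lo < o.end for o in orfs
        ):
            seq[lo : lo + 3] = list("TAA")

    features = []
    for orf in orfs:
        prot = translate_nt("".join(seq[orf.start : orf.end - 3]))
        features.append(Feature(orf.role, orf.start, orf.end, "+", prot))
    return "".join(seq), features


def _owner_orfs(orfs: Sequence[OrfSpec], lo: int, hi: int, exclude: OrfSpec) -> list[OrfSpec]:
    return [o for o in orfs if o is not exclude and o.start < hi and lo < o.end]


def _repair_overlaps(
    seq: list[str], orfs: Sequence[OrfSpec], template: GenomeTemplate,
    rng: np.random.Generator, max_rounds: int = 200
) -> None:
    novel_roles = {o.role for o in orfs if o.role == "novel"}
    for _ in range(max_rounds):
        violation = None
        for orf in orfs:
            v = _orf_violations(seq, orf)
            if v:
                violation = (orf, v[0])
                break
        if violation is None:
            return
        orf, (kind, pos) = violation
        owners = _owner_orfs(orfs, pos, pos + 3, orf)
        if not owners:
            # free region: rewrite the codon directly
            if kind == "start":
                seq[pos : pos + 3] = list("ATG")
            elif kind == "stop":
                seq[pos : pos + 3] = list("TAA")
            else:
                aa_choices = [c for c in CODONS_FOR_AA["L"]]
                seq[pos : pos + 3] = list(aa_choices[0])
            continue
        owner = owners[0]
        if not _recode_owner(seq, owner, orf, kind, pos, owner.role in novel_roles):
            raise TemplateError(
                f"template {template.name!r}: overlap of {orf.role!r} with "
                f"{owner.role!r} forces an un-repairable {kind} at nt {pos}"
            )
    raise TemplateError(
        f"template {template.name!r}: overlap constraints did not converge"
    )


def _recode_owner(
    seq: list[str], owner: OrfSpec, target: OrfSpec, kind: str, pos: int,
    owner_is_free: bool,
) -> bool:
    """Try codon choices of ``owner`` covering nt [pos, pos+3) so that the
    ``target`` ORF gets a valid codon there, without breaking ``owner``."""
    first = owner.start + ((pos - owner.start) // 3) * 3
    codon_starts = [p for p in range(first, min(pos + 3, owner.end), 3) if p >= owner.start]
    if not codon_starts:
        return False
    options: list[list[str]] = []
    for cs in codon_starts:
        current = "".join(seq[cs : cs + 3])
        if owner_is_free:
            opts = [c for c in AA_FOR_CODON if c not in STOP_CODONS]
        else:
            aa = AA_FOR_CODON.get(current)
            if aa is None or aa == "*":
                opts = [c for c in AA_FOR_CODON if c not in STOP_CODONS]
            else:
                opts = list(CODONS_FOR_AA[aa])
        options.append(opts)

    if kind == "start":
        wanted = set(START_CODONS)
    elif kind == "stop":
        wanted = set(STOP_CODONS)
    else:
        wanted = {c for c in AA_FOR_CODON if c not in STOP_CODONS}

    def assign(combo: Sequence[str]) -> None:
        for cs, codon in zip(codon_starts, combo):
            hi = min(cs + 3, owner.end)
            for k in range(cs, hi):
                seq[k] = codon[k - cs]

    saved = [seq[p] for p in range(codon_starts[0], min(codon_starts[-1] + 3, owner.end))]
    import itertools

    for combo in itertools.product(*options):
        assign(combo)
        if "".join(seq[pos : pos + 3]) not in wanted:
            continue
        # owner must stay stop-free in its own frame across the touched span
        ok = True
        for cs in codon_starts:
            if cs + 3 <= owner.end - 3 and "".join(seq[cs : cs + 3]) in STOP_CODONS:
                ok = False
                break
        if ok:
            return True
    lo = codon_starts[0]
    for k, base in enumerate(saved):
        seq[lo + k] = base
    return False


def translate_nt(coding: str) -> str:
    return "".join(
        AA_FOR_CODON.get(coding[i : i + 3], "X")
        for i in range(0, len(coding) - len(coding) % 3, 3)
    )


# ---------------------------------------------------------------------------
# population-level divergence


def evolve_population(
    ancestor: str,
    target_identity: float,
    n: int,
    seed: int,
    protect: Iterable[int] = (),
) -> list[str]:
    """``n`` substitution-only variants of ``ancestor`` whose identity to it
    equals ``target_identity`` (fixed substitution count, distinct sites,
    uniform choice among the three alternative bases)."""
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(ancestor)
    protected = set(protect)
    mutable = np.array([i for i in range(L) if i not in protected], dtype=np.int64)
    k = round((1.0 - target_identity) * L)
    if k > mutable.size:
        raise ValueError("target divergence exceeds mutable sites")
    out = []
    for _ in range(n):
        variant = list(ancestor)
        sites = rng.choice(mutable, size=k, replace=False)
        for s in sites:
            cur = variant[s]
            alts = [b for b in _BASES if b != cur]
            variant[s] = alts[rng.integers(0, 3)]
        out.append("".join(variant))
    return out


def _pairwise_identity(m: float) -> float:
    """Expected per-site agreement of two copies independently substituted
    with probability m (uniform among the 3 alternative bases)."""
    return (1.0 - m) ** 2 + m * m / 3.0


def _branch_rate_for_pairwise(p_eq: float) -> float:
    """Per-branch substitution probability m so that two independently
    diverged copies agree at a site with probability p_eq:
    (1-m)^2 + m^2/3 = p_eq.  Saturates at m=0.75 (p_eq floor 1/4)."""
    if p_eq >= 1.0:
        return 0.0
    if p_eq <= 0.25:
        return 0.75
    disc = 4.0 - (16.0 / 3.0) * (1.0 - p_eq)
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


# Anchor (motif) sites diverge between phylotypes too, just several-fold
# slower than the rest of the gene - full conservation would make short
# motif-spanning gene fragments look spuriously similar across phylotypes.
ANCHOR_RATE_FACTOR = 0.4


def _region_rates(L: int, C: int, target: float) -> tuple[float, float]:
    """Per-branch substitution rates (non-anchor, anchor) for a region of
    ``L`` sites with ``C`` anchor sites so that the expected pairwise
    identity of two branches equals ``target`` (anchors evolving at
    ``ANCHOR_RATE_FACTOR`` times the non-anchor rate).  Saturates at the
    mutational floor."""

    def realized(m: float) -> float:
        pa = _pairwise_identity(min(ANCHOR_RATE_FACTOR * m, 0.75))
        pn = _pairwise_identity(m)
        return (C * pa + (L - C) * pn) / L

    if target >= 1.0:
        return 0.0, 0.0
    if realized(0.75) >= target:
        return 0.75, min(ANCHOR_RATE_FACTOR * 0.75, 0.75)
    lo, hi = 0.0, 0.75
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) > target:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    return m, min(ANCHOR_RATE_FACTOR * m, 0.75)


def _anchor_nt_positions(features: Sequence[Feature]) -> set[int]:
    """Nucleotide positions of domain anchor windows on a genome."""
    conserved: set[int] = set()
    for feat in features:
        model_name = _ROLE_TO_MODEL.get(feat.role)
        if model_name is None:
            continue
        model = _motifs.domain_model(model_name)
        capacity = len(feat.protein)
        for s, e in model.anchors.values():
            if e > capacity:
                continue
            conserved.update(range(feat.start + 3 * s, feat.start + 3 * e))
    return conserved


def _diverge_regions(
    root: str,
    features: Sequence[Feature],
    pairwise_target: float,
    conserved: set[int],
    rng: np.random.Generator,
) -> str:
    """One branch of anchored divergence from the root: per region (each ORF
    and the non-ORF remainder) substitute at non-anchor sites at the rate
    that realizes ``pairwise_target`` between two such branches.

    Phylotype ancestors represent distinct species, not sequencing noise,
    so their reading frames stay intact: ORF start/stop codons are held
    fixed and any in-frame stop a substitution would create is re-drawn.
    """
    L = len(root)
    protected = set(conserved)
    for feat in features:
        protected.update(range(feat.start, feat.start + 3))
        protected.update(range(feat.end - 3, feat.end))
    covered = np.zeros(L, dtype=bool)
    regions: list[np.ndarray] = []
    for feat in features:
        idx = np.arange(feat.start, feat.end)
        regions.append(idx)
        covered[idx] = True
    rest = np.flatnonzero(~covered)
    if rest.size:
        regions.append(rest)

    out = list(root)
    frame_fixed = protected - conserved  # start/stop codons: never mutate
    for idx in regions:
        anchor = np.array(
            [i for i in idx if i in conserved and i not in frame_fixed],
            dtype=np.int64,
        )
        free = np.array(
            [i for i in idx if i not in conserved and i not in frame_fixed],
            dtype=np.int64,
        )
        if free.size == 0 and anchor.size == 0:
            continue
        Lr = anchor.size + free.size
        m_free, m_anchor = _region_rates(Lr, anchor.size, pairwise_target)
        for sites_pool, rate in ((free, m_free), (anchor, m_anchor)):
            k = round(rate * sites_pool.size)
            if k == 0:
                continue
            sites = rng.choice(sites_pool, size=k, replace=False)
            for s in sites:
                alts = [b for b in _BASES if b != out[s]]
                out[s] = alts[rng.integers(0, 3)]

    # re-draw substitutions that created in-frame stops inside an ORF
    for feat in features:
        for p in range(feat.start, feat.end - 3, 3):
            codon = out[p] + out[p + 1] + out[p + 2]
            if codon not in STOP_CODONS:
                continue
            fixed = False
            for off in range(3):
                site = p + off
                if site in frame_fixed or out[site] == root[site]:
                    continue
                for alt in _BASES:
                    if alt in (out[site], root[site]):
                        continue
                    trial = list(codon)
                    trial[off] = alt
                    if "".join(trial) not in STOP_CODONS:
                        out[site] = alt
                        fixed = True
                        break
                if fixed:
                    break
            if not fixed:
                # fall back to reverting one mutated site
                for off in range(3):
                    site = p + off
                    if out[site] != root[site]:
                        out[site] = root[site]
                        break
    return "".join(out)


# ---------------------------------------------------------------------------
# community spec and containers


@dataclass
class SyntheticCommunitySpec:
    """Study conditions for one synthetic community."""

    n_phylotypes: int = 12
    within_phylotype_identity: float = 0.90
    between_phylotype_identity: float = 0.50
    variants_per_phylotype: int = 1
    read_length_nt: int = 200
    coverage: float = 20.0
    substitution_error_rate: float = 0.01
    background_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phylotypes < 1 or self.variants_per_phylotype < 1:
            raise ValueError("n_phylotypes and variants_per_phylotype must be >= 1")
        if not (0.70 < self.within_phylotype_identity <= 1.0):
            raise ValueError("within_phylotype_identity must be in (0.70, 1.0]")
        if not (0.0 <= self.between_phylotype_identity < 0.70):
            raise ValueError("between_phylotype_identity must be in [0, 0.70)")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length_nt <= 0:
            raise ValueError("read_length_nt must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SimulatedGenome:
    id: str
    sequence: str
    features: list[Feature]
    phylotype: str
    is_reference: bool

    def gene(self, role: str) -> str | None:
        for f in self.features:
            if f.role == role:
                return self.sequence[f.start : f.end]
        return None


@dataclass
class SimRead:
    id: str
    sequence: str


@dataclass
class TruthTable:
    """Ground truth: genome -> phylotype/features, read -> origin."""

    genomes: dict[str, SimulatedGenome]
    reads: dict[str, dict]

    def phylotype_of_read(self, read_id: str) -> str:
        return self.reads[read_id]["phylotype"]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tid\tphylotype\tgenome\tstart\tstrand\n")
            for gid, g in sorted(self.genomes.items()):
                fh.write(f"genome\t{gid}\t{g.phylotype}\t{gid}\t0\t+\n")
            for rid, rec in sorted(self.reads.items()):
                fh.write(
                    f"read\t{rid}\t{rec['phylotype']}\t{rec['genome']}\t"
                    f"{rec['start']}\t{rec['strand']}\n"
                )


@dataclass
class Community:
    spec: SyntheticCommunitySpec
    template: GenomeTemplate
    root_sequence: str
    genomes: list[SimulatedGenome]

    def genome(self, gid: str) -> SimulatedGenome:
        for g in self.genomes:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def phylotypes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.genomes:
            out.setdefault(g.phylotype, []).append(g.id)
        return out


def make_community(
    spec: SyntheticCommunitySpec, template: GenomeTemplate | None = None
) -> Community:
    """Plant ``n_phylotypes`` phylotypes (reference + truncated variants)
    at the configured within/between identities."""
    template = template or default_template()
    root_seed = int(np.random.default_rng(spec.seed).integers(0, 2**31 - 1))
    root_seq, root_features = simulate_genome(template, root_seed)
    conserved = _anchor_nt_positions(root_features)
    rng = np.random.default_rng([spec.seed, 1])

    utr5 = min(f.start for f in root_features)
    utr3 = len(root_seq) - max(f.end for f in root_features)
    genomes: list[SimulatedGenome] = []
    for i in range(spec.n_phylotypes):
        label = f"pt{i:02d}"
        anc = _diverge_regions(
            root_seq, root_features, spec.between_phylotype_identity, conserved, rng
        )
        ref_id = f"{label}_g00"
        genomes.append(SimulatedGenome(ref_id, anc, list(root_features), label, True))
        if spec.variants_per_phylotype > 1:
            var_seed = int(rng.integers(0, 2**31 - 1))
            variants = evolve_population(
                anc, spec.within_phylotype_identity,
                spec.variants_per_phylotype - 1, var_seed,
            )
            for j, vseq in enumerate(variants, start=1):
                cut_left = int(rng.integers(1, max(2, min(120, utr5))))
                cut_right = int(rng.integers(1, max(2, min(120, utr3))))
                trimmed = vseq[cut_left : len(vseq) - cut_right]
                feats = [
                    Feature(f.role, f.start - cut_left, f.end - cut_left, f.strand, f.protein)
                    for f in root_features
                ]
                genomes.append(
                    SimulatedGenome(f"{label}_g{j:02d}", trimmed, feats, label, False)
                )
    return Community(spec, template, root_seq, genomes)


def shotgun_reads(
    genomes: Sequence[tuple[str, str]] | Community,
    spec: SyntheticCommunitySpec,
    abundances: Sequence[float] | None = None,
    truth_phylotypes: dict[str, str] | None = None,
) -> tuple[list[SimRead], TruthTable]:
    """Poisson shotgun sampling of the genomes, both strands, uniform
    positions, substitution errors at the configured rate, plus random
    background reads labelled ``background`` in the truth table."""
    if isinstance(genomes, Community):
        community = genomes
        pairs = [(g.id, g.sequence) for g in community.genomes]
        truth_phylotypes = {g.id: g.phylotype for g in community.genomes}
        genome_truth = {g.id: g for g in community.genomes}
    else:
        pairs = list(genomes)
        truth_phylotypes = truth_phylotypes or {gid: gid for gid, _ in pairs}
        genome_truth = {
            gid: SimulatedGenome(gid, seq, [], truth_phylotypes[gid], True)
            for gid, seq in pairs
        }
    if not pairs:
        raise ValueError("no genomes to sample")
    if spec.read_length_nt > min(len(s) for _, s in pairs):
        raise ValueError("read_length_nt exceeds the shortest genome")
    if abundances is None:
        abundances = [1.0] * len(pairs)
    rng = np.random.default_rng([spec.seed, 2])
    rl = spec.read_length_nt
    err = spec.substitution_error_rate

    reads: list[SimRead] = []
    truth_reads: dict[str, dict] = {}
    counter = 0

    def emit(seq: str, rec: dict) -> None:
        nonlocal counter
        rid = f"read{counter:06d}"
        counter += 1
        reads.append(SimRead(rid, seq))
        truth_reads[rid] = rec

    for (gid, gseq), ab in zip(pairs, abundances):
        lam = spec.coverage * ab * len(gseq) / rl
        n = int(rng.poisson(lam))
        for _ in range(n):
            start = int(rng.integers(0, len(gseq) - rl + 1))
            frag = gseq[start : start + rl]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            if err > 0:
                frag_l = list(frag)
                hits = np.flatnonzero(rng.random(rl) < err)
                for h in hits:
                    alts = [b for b in _BASES if b != frag_l[h]]
                    frag_l[h] = alts[rng.integers(0, 3)]
                frag = "".join(frag_l)
            emit(frag, {"genome": gid, "phylotype": truth_phylotypes[gid],
                        "start": start, "strand": strand})

    n_phage = counter
    bf = spec.background_fraction
    if bf > 0 and n_phage > 0:
        n_bg = int(rng.poisson(n_phage * bf / (1.0 - bf)))
        for _ in range(n_bg):
            frag = "".join(_BASES[i] for i in rng.integers(0, 4, size=rl))
            emit(frag, {"genome": "background", "phylotype": "background",
                        "start": -1, "strand": "+"})
    return reads, TruthTable(genomes=genome_truth, reads=truth_reads)


# ---------------------------------------------------------------------------
# serialization


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path, quality_char: str = "?") -> None:
    """FASTQ with a constant Q30 quality string."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_gff3(community: Community, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in community.genomes:
            for f in g.features:
                fh.write(
                    f"{g.id}\trnaphage\tCDS\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t"
                    f"ID={g.id}.{f.role};product={f.role}\n"
                )


def write_community(
    community: Community,
    reads: Sequence[SimRead],
    truth: TruthTable,
    out_dir,
    fastq: bool = False,
) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": str(out / "genomes.fasta"),
        "reads": str(out / ("reads.fastq" if fastq else "reads.fasta")),
        "features": str(out / "features.gff3"),
        "truth": str(out / "truth.tsv"),
        "spec": str(out / "spec.json"),
    }
    write_fasta([(g.id, g.sequence) for g in community.genomes], paths["genomes"])
    if fastq:
        write_fastq([(r.id, r.sequence) for r in reads], paths["reads"])
    else:
        write_fasta([(r.id, r.sequence) for r in reads], paths["reads"])
    write_gff3(community, paths["features"])
    truth.to_tsv(paths["truth"])
    Path(paths["spec"]).write_text(community.spec.to_json() + "\n")
    return paths
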