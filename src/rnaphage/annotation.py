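"""ORF prediction and domain-based partial-genome classification.

A partial genome is an assembled contig longer than 750 nt whose
translation contains a recognizable phage-specific domain (RdRp, coat,
maturation, NTPase, ...).  ORFs are predicted in all six frames with the
bacterial start-codon set (ATG/GTG/TTG, standard genetic code); ORFs
truncated by a contig edge are reported with partial flags and still
count toward domain scanning, since real partial genomes truncate genes.
RdRp hits additionally record which of the five palm motifs (A-E) the
match covers; palm completeness gates phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import motifs as _motifs
from .assembly import Contig
from .synthetic_community import (
    AA_FOR_CODON,
    START_CODONS,
    STOP_CODONS,
    revcomp,
)

PHAGE_DOMAINS = (
    "rdrp_ss", "maturation", "coat", "lysin", "rdrp_ds", "ntpase",
    "peptidoglycan_hydrolase",
)


@dataclass(frozen=True)
class Orf:
    contig_id: str
    start: int            # 0-based half-open on the contig forward strand;
    end: int              # includes start codon and (if complete) stop codon
    strand: str
    frame: int            # +1..+3 / -1..-3
    protein: str          # no terminal '*'
    partial_5p: bool = False
    partial_3p: bool = False

    @property
    def complete(self) -> bool:
        return not (self.partial_5p or self.partial_3p)


@dataclass(frozen=True)
class DomainHit:
    orf: Orf
    domain: str
    score: float
    motif_coverage: frozenset[str] = frozenset()


@dataclass
class PartialGenome:
    contig: Contig
    orfs: list[Orf]
    hits: list[DomainHit]

    @property
    def has_rdrp(self) -> bool:
        return any(h.domain in ("rdrp_ss", "rdrp_ds") for h in self.hits)

    @property
    def has_maturation(self) -> bool:
        return any(h.domain == "maturation" for h in self.hits)

    def gene_region(self, domain: str) -> Orf | None:
        """ORF carrying the best-scoring hit for ``domain``."""
        best = None
        for h in self.hits:
            if h.domain == domain and (best is None or h.score > best.score):
                best = h
        return best.orf if best else None


def _translate(codons: str) -> str:
    return "".join(
        AA_FOR_CODON.get(codons[i : i + 3], "X") for i in range(0, len(codons), 3)
    )


def find_orfs(
    contig: str,
    min_aa: int = 50,
    contig_id: str = "contig",
    start_codons: Sequence[str] = START_CODONS,
) -> list[Orf]:
    """All maximal ORFs in six frames with protein length >= ``min_aa``.

    Within each frame, stop codons partition the codon sequence into
    segments.  An internal segment yields one ORF, from its first start
    codon to the stop.  A segment at the frame's 5' edge is reported from
    the frame start with ``partial_5p`` set (its true start may lie off the
    contig); a segment that runs off the 3' end is reported from its first
    start codon with ``partial_3p`` set.  Coordinates are given on the
    forward strand of the contig.
    """
    seq = contig.upper()
    L = len(seq)
    if L < 3:
        return []
    out: list[Orf] = []
    for strand, src in (("+", seq), ("-", revcomp(seq))):
        for off in range(3):
            frame = (off + 1) if strand == "+" else -(off + 1)
            ncod = (L - off) // 3
            if ncod == 0:
                continue
            codons = [src[off + 3 * i : off + 3 * i + 3] for i in range(ncod)]
            seg_start = 0  # codon index where the current segment begins
            at_edge = True
            i = 0
            while i <= ncod:
                is_stop = i < ncod and codons[i] in STOP_CODONS
                if is_stop or i == ncod:
                    seg_end = i  # exclusive, codon index of the stop
                    orf = _segment_orf(
                        codons, seg_start, seg_end, stop_present=is_stop,
                        at_edge=at_edge, start_codons=start_codons,
                    )
                    if orf is not None:
                        c0, c1, partial5, partial3, prot = orf
                        if len(prot) >= min_aa:
                            s_local = off + 3 * c0
                            e_local = off + 3 * c1
                            if strand == "+":
                                s, e = s_local, e_local
                            else:
                                s, e = L - e_local, L - s_local
                            out.append(
                                Orf(contig_id, s, e, strand, frame, prot,
                                    partial5, partial3)
                            )
                    seg_start = i + 1
                    at_edge = False
                i += 1
    out.sort(key=lambda o: (o.start, o.end, o.frame))
    return out


def _segment_orf(codons, seg_start, seg_end, stop_present, at_edge, start_codons):
    """Resolve one stop-bounded segment into (codon_start, codon_end_excl,
    partial_5p, partial_3p, protein) or None."""
    if seg_end <= seg_start:
        return None
    if at_edge:
        c0 = seg_start
        partial5 = True
    else:
        c0 = None
        for c in range(seg_start, seg_end):
            if codons[c] in start_codons:
                c0 = c
                break
        if c0 is None:
            return None
        partial5 = False
    if stop_present:
        prot = _translate("".join(codons[c0:seg_end]))
        return (c0, seg_end + 1, partial5, False, prot)
    prot = _translate("".join(codons[c0:seg_end]))
    if not prot:
        return None
    return (c0, seg_end, partial5, True, prot)


def measure_orf_overlap(a: Orf, b: Orf) -> int:
    """Coordinate overlap of two ORFs on the same contig, in nucleotides."""
    if a.contig_id != b.contig_id:
        raise ValueError(
            f"ORFs on different contigs: {a.contig_id!r} vs {b.contig_id!r}"
        )
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def scan_domains(
    orf: Orf,
    models: dict[str, _motifs.DomainModel] | None = None,
) -> list[DomainHit]:
    """Score an ORF's protein against domain models; return above-threshold
    hits.  RdRp hits annotate which palm motifs (A-E) are matched."""
    models = models if models is not None else _motifs.default_models()
    hits = []
    for name in sorted(models):
        model = models[name]
        if not isinstance(model, _motifs.DomainModel):
            raise TypeError(f"not a domain model: {name!r}")
        scan = model.scan(orf.protein)
        if scan.is_hit:
            hits.append(
                DomainHit(
                    orf=orf,
                    domain=name,
                    score=scan.score,
                    motif_coverage=scan.motifs if name.startswith("rdrp") else frozenset(),
                )
            )
    return hits


def palm_complete(hit: DomainHit) -> bool:
    """True when an RdRp hit covers all five palm motifs A-E."""
    if not hit.domain.startswith("rdrp"):
        raise ValueError(f"palm completeness is defined for RdRp hits, got {hit.domain!r}")
    return hit.motif_coverage >= _motifs.PALM_MOTIFS


@dataclass
class ClassificationSummary:
    n_partial_genomes: int
    n_with_rdrp: int
    n_with_maturation: int
    n_with_both: int


def classify_partial_genomes(
    contigs: Sequence[Contig],
    orfs_by_contig: dict[str, list[Orf]] | None = None,
    hits_by_contig: dict[str, list[DomainHit]] | None = None,
    min_len: int = 750,
    min_aa: int = 50,
    models: dict[str, _motifs.DomainModel] | None = None,
) -> tuple[list[PartialGenome], ClassificationSummary]:
    """Partial genomes: contigs > ``min_len`` nt with >= 1 phage domain hit.

    When ``orfs_by_contig`` / ``hits_by_contig`` are omitted they are
    computed here.  Returns accepted partial genomes plus summary domain
    tallies over the accepted set.
    """
    accepted: list[PartialGenome] = []
    for contig in contigs:
        if len(contig.sequence) <= min_len:
            continue
        if orfs_by_contig is not None and contig.id in orfs_by_contig:
            orfs = orfs_by_contig[contig.id]
        else:
            orfs = find_orfs(contig.sequence, min_aa=min_aa, contig_id=contig.id)
        if hits_by_contig is not None and contig.id in hits_by_contig:
            hits = hits_by_contig[contig.id]
        else:
            hits = [h for orf in orfs for h in scan_domains(orf, models=models)]
        if hits:
            accepted.append(PartialGenome(contig, orfs, hits))
    summary = ClassificationSummary(
        n_partial_genomes=len(accepted),
        n_with_rdrp=sum(pg.has_rdrp for pg in accepted),
        n_with_maturation=sum(pg.has_maturation for pg in accepted),
        n_with_both=sum(pg.has_rdrp and pg.has_maturation for pg in accepted),
    )
    return accepted, summary
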