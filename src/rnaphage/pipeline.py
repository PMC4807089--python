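"""End-to-end orchestration: simulate -> triage -> assemble -> annotate ->
dereplicate -> species table -> tree, as one reproducible run.

Every stage writes plain files (FASTA/TSV/JSON/Newick) into the run
directory and logs one structured line of counts; ``manifest.json``
records every parameter (defaults are the discovery thresholds: E-value
1e-4, >= 10 significant reads, contigs > 750 nt, phylotype identity
> 0.70, species cutoffs 70/60/50/40, 100 bootstrap replicates) plus a
content hash per output, so identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import motifs as _motifs
from .annotation import classify_partial_genomes
from .assembly import filter_contigs, greedy_assemble, write_contigs_fasta
from .dereplication import (
    GeneSet,
    cluster_phylotypes,
    species_table,
    write_phylotypes_tsv,
)
from .homology import (
    SearchParams,
    translated_search,
    triage_dataset,
    write_hits_tsv,
    write_triage_json,
)
from .identity import IdentityMatrix
from .phylo import DistanceMatrix, nj_tree
from .synthetic_community import (
    SyntheticCommunitySpec,
    make_community,
    revcomp,
    shotgun_reads,
    write_community,
)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the discovery rules' values."""

    evalue: float = 1e-4
    min_reads: int = 10
    min_contig: int = 750
    min_overlap: int = 30
    max_mismatch_rate: float = 0.08
    min_orf_aa: int = 50
    phylotype_threshold: float = 0.70
    phylotype_gene: str = "either"
    min_gene_aligned: int = 450   # aligned nt needed before a gene pair
                                  # can support a phylotype link
    species_cutoffs: tuple[float, ...] = (70, 60, 50, 40)
    bootstrap: int = 100
    seed: int = 0
    community: SyntheticCommunitySpec = field(default_factory=SyntheticCommunitySpec)

    def __post_init__(self) -> None:
        if isinstance(self.community, dict):
            self.community = SyntheticCommunitySpec(**self.community)
        self.community.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    status: str
    counts: dict
    out_dir: str
    phylotypes: list = field(default_factory=list)
    partial_genomes: list = field(default_factory=list)
    species_counts: dict = field(default_factory=dict)
    newick: str | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _gene_sets(partial_genomes) -> list[GeneSet]:
    out = []
    for pg in partial_genomes:
        genes = {}
        for role, domains in (("rdrp", ("rdrp_ss", "rdrp_ds")), ("maturation", ("maturation",))):
            best = None
            for d in domains:
                orf = pg.gene_region(d)
                if orf is not None:
                    best = orf
                    break
            if best is not None:
                nt = pg.contig.sequence[best.start : best.end]
                genes[role] = nt if best.strand == "+" else revcomp(nt)
        if genes:
            out.append(GeneSet(pg.contig.id, len(pg.contig.sequence), genes))
    return out


def run_pipeline(cfg: RunConfig, out_dir) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    counts: dict = {}

    def log(stage: str, **kv) -> None:
        counts[stage] = kv
        line = json.dumps({"stage": stage, **kv}, sort_keys=True)
        log_lines.append(line)
        print(line)

    # --- simulate -----------------------------------------------------
    community = make_community(cfg.community)
    reads, truth = shotgun_reads(community, cfg.community)
    paths = write_community(community, reads, truth, out)
    log("simulate", n_genomes=len(community.genomes), n_reads=len(reads),
        n_phylotypes=cfg.community.n_phylotypes)

    # --- triage -------------------------------------------------------
    queries = list(_motifs.reference_proteins().items())
    read_pairs = [(r.id, r.sequence) for r in reads]
    hits = translated_search(queries, read_pairs, SearchParams(),
                             evalue_cutoff=cfg.evalue)
    decision = triage_dataset(hits, dataset_id="synthetic",
                              min_reads=cfg.min_reads, evalue_cutoff=cfg.evalue)
    write_hits_tsv(hits, out / "hits.tsv")
    write_triage_json(decision, out / "triage.json")
    log("triage", n_hits=len(hits),
        n_significant_reads=decision.n_significant_reads,
        selected=decision.selected)
    if not decision.selected:
        _write_manifest(cfg, out, counts, "not_selected", log_lines)
        return PipelineResult("not_selected", counts, str(out))

    # --- assemble -----------------------------------------------------
    contigs = greedy_assemble(read_pairs, min_overlap=cfg.min_overlap,
                              max_mismatch_rate=cfg.max_mismatch_rate,
                              source_dataset="synthetic")
    kept = filter_contigs(contigs, min_len=cfg.min_contig)
    write_contigs_fasta(kept, out / "contigs.fasta")
    log("assemble", n_contigs=len(contigs), n_contigs_kept=len(kept))

    # --- annotate -----------------------------------------------------
    partial_genomes, summary = classify_partial_genomes(
        kept, min_len=cfg.min_contig, min_aa=cfg.min_orf_aa
    )
    log("annotate", n_partial_genomes=summary.n_partial_genomes,
        n_with_rdrp=summary.n_with_rdrp,
        n_with_maturation=summary.n_with_maturation,
        n_with_both=summary.n_with_both)

    # --- dereplicate --------------------------------------------------
    gene_sets = _gene_sets(partial_genomes)
    phylotypes = cluster_phylotypes(gene_sets, gene=cfg.phylotype_gene,
                                    threshold=cfg.phylotype_threshold,
                                    min_aligned=cfg.min_gene_aligned)
    lengths = {g.genome_id: g.length for g in gene_sets}
    write_phylotypes_tsv(phylotypes, lengths, out / "phylotypes.tsv")
    # phylotype count anchored on unique RdRp domains: maturation-only
    # clusters may be pieces of an already-counted genome, so only
    # clusters with an RdRp-bearing member count as distinct phylotypes
    genes_by_id = {g.genome_id: g.genes for g in gene_sets}
    rdrp_clusters = [
        pt for pt in phylotypes
        if any("rdrp" in genes_by_id[m] for m in pt.members)
    ]
    log("dereplicate", n_clusters=len(phylotypes),
        n_phylotypes_rdrp=len(rdrp_clusters))

    # --- species table ------------------------------------------------
    rdrp_prots = []
    by_id = {pg.contig.id: pg for pg in partial_genomes}
    for pt in rdrp_clusters:
        # longest RdRp gene among the cluster's members represents it
        best = None
        for m in sorted(pt.members):
            pg = by_id[m]
            for d in ("rdrp_ss", "rdrp_ds"):
                orf = pg.gene_region(d)
                if orf is not None and (best is None or len(orf.protein) > len(best[1])):
                    best = (m, orf.protein)
        if best is not None:
            rdrp_prots.append(best)
    species_counts: dict = {}
    newick = None
    if len(rdrp_prots) >= 2:
        matrix = IdentityMatrix.from_sequences(rdrp_prots, alphabet="aa")
        table = species_table(matrix, cutoffs=cfg.species_cutoffs)
        table.to_tsv(out / "species_table.tsv")
        species_counts = {f"{c:g}": n for c, n in table.counts.items()}
        if len(rdrp_prots) >= 3:
            dvals = 1.0 - matrix.identity
            np.fill_diagonal(dvals, 0.0)
            tree = nj_tree(DistanceMatrix(matrix.names, dvals))
            newick = tree.newick()
            (out / "tree.nwk").write_text(newick + "\n")
    log("species", species_counts=species_counts, n_rdrp_proteins=len(rdrp_prots))

    _write_manifest(cfg, out, counts, "completed", log_lines)
    return PipelineResult("completed", counts, str(out), phylotypes,
                          partial_genomes, species_counts, newick)


def _write_manifest(cfg, out: Path, counts: dict, status: str, log_lines) -> None:
    manifest = {
        "status": status,
        "config": asdict(cfg),
        "models_version": _motifs.MODELS_VERSION,
        "counts": counts,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
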