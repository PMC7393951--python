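"""Ortholog gene-cluster inference and unique-cluster functional analysis.

Gene clusters (orthogroups) are built from reciprocal-best-hit (RBH) edges
between genomes — each gene must be the other's best-scoring hit in the
partner genome — plus high-identity within-genome edges for paralogs, then
taken as connected components.  Each cluster is annotated with the
functional category most frequent among its members; clusters whose member
genomes are all focal are "unique" clusters, and their category
composition is compared with the composition of the full annotated pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
from scipy.stats import mannwhitneyu

from ._align import ProteinSet, alignment_score, global_identity
from .core import GeneRecord, GenomeRecord, Role

__all__ = [
    "GeneCluster",
    "CompositionTable",
    "global_protein_identity",
    "build_rbh_graph",
    "cluster_genes",
    "assign_cluster_category",
    "unique_clusters",
    "functional_composition",
    "marker_density_compare",
]


@dataclass
class GeneCluster:
    cluster_id: str
    member_gene_ids: set[str]
    member_genome_ids: set[str]
    category: Optional[str] = None
    unique_to_focal: bool = False


@dataclass
class CompositionTable:
    """Per-category proportions among annotated unique clusters and among
    all annotated clusters; each proportion column sums to 1 over the
    categories present."""

    unique_proportion: dict[str, float] = field(default_factory=dict)
    total_proportion: dict[str, float] = field(default_factory=dict)
    n_unique_annotated: int = 0
    n_total_annotated: int = 0
    annotated_fraction: float = 0.0


def global_protein_identity(protein_a: str, protein_b: str) -> tuple[float, float]:
    """Global BLOSUM62 alignment (affine gaps, open 11 / extend 1).

    Identity is matches over aligned columns, counting gap columns.
    Returns (identity percent, alignment score).
    """
    return global_identity(protein_a, protein_b)


def build_rbh_graph(
    proteomes: dict[str, dict[str, str]],
    min_identity: float = 30.0,
    min_shorter_coverage: float = 0.5,
    kmer_prefilter: int = 4,
    paralog_min_identity: float = 70.0,
    max_candidates: Optional[int] = 50,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit edges between genes of different genomes.

    ``proteomes`` maps genome_id -> {gene_id: protein}.  Candidate pairs
    must share at least one exact ``kmer_prefilter``-mer; an edge requires
    each gene to be the other's best-scoring hit in the partner genome and
    the pair to pass the identity and shorter-sequence-coverage thresholds.
    Within-genome edges bridge paralog pairs above ``paralog_min_identity``.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two genomes")
    genome_ids = sorted(proteomes)
    indexes = {g: ProteinSet(proteomes[g], k=kmer_prefilter) for g in genome_ids}

    # best hit of each gene in each partner genome, by alignment score
    best: dict[tuple[str, str], tuple[str, float]] = {}
    for ga in genome_ids:
        for gb in genome_ids:
            if ga == gb:
                continue
            index_b = indexes[gb]
            for gid, prot in proteomes[ga].items():
                top: Optional[tuple[str, float]] = None
                for cand in index_b.candidates(prot, max_candidates):
                    s = alignment_score(prot, index_b.proteins[cand])
                    if top is None or s > top[1] or (s == top[1] and cand < top[0]):
                        top = (cand, s)
                if top is not None:
                    best[(gid, gb)] = top

    edges: list[tuple[str, str]] = []
    for ia, ga in enumerate(genome_ids):
        for gb in genome_ids[ia + 1 :]:
            for gid_a, prot_a in proteomes[ga].items():
                hit = best.get((gid_a, gb))
                if hit is None:
                    continue
                gid_b = hit[0]
                back = best.get((gid_b, ga))
                if back is None or back[0] != gid_a:
                    continue
                prot_b = proteomes[gb][gid_b]
                identity, _ = global_identity(prot_a, prot_b)
                shorter = min(len(prot_a), len(prot_b))
                longer = max(len(prot_a), len(prot_b))
                coverage = shorter / longer
                if identity >= min_identity and coverage >= min_shorter_coverage:
                    edges.append((gid_a, gid_b))

    # within-genome paralog bridging; a cheap score screen (relative to the
    # self-alignment scores) avoids full alignments of unrelated pairs
    for g in genome_ids:
        ids = sorted(proteomes[g])
        index = indexes[g]
        self_score = {gid: alignment_score(proteomes[g][gid], proteomes[g][gid]) for gid in ids}
        for gid_a in ids:
            prot_a = proteomes[g][gid_a]
            for gid_b in index.candidates(prot_a, max_candidates):
                if gid_b <= gid_a:
                    continue
                prot_b = proteomes[g][gid_b]
                s = alignment_score(prot_a, prot_b)
                if s < 0.4 * min(self_score[gid_a], self_score[gid_b]):
                    continue
                identity, _ = global_identity(prot_a, prot_b)
                if identity > paralog_min_identity:
                    edges.append((gid_a, gid_b))
    return edges


def cluster_genes(edges: Sequence[tuple[str, str]], genes: Sequence[GeneRecord]) -> list[GeneCluster]:
    """Connected components of the RBH graph; edge-less genes become
    singleton clusters.  The clusters partition the gene set."""
    genome_of = {g.gene_id: g.genome_id for g in genes}
    graph = nx.Graph()
    graph.add_nodes_from(genome_of)
    for a, b in edges:
        if a not in genome_of or b not in genome_of:
            raise KeyError(f"edge references unknown gene: ({a}, {b})")
        graph.add_edge(a, b)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    clusters = []
    for i, members in enumerate(components):
        clusters.append(
            GeneCluster(
                cluster_id=f"GC{i + 1:05d}",
                member_gene_ids=set(members),
                member_genome_ids={genome_of[m] for m in members},
            )
        )
    return clusters


def assign_cluster_category(cluster: GeneCluster, annotations: dict[str, str]) -> Optional[str]:
    """Majority category among annotated members; ties broken by the
    lexicographically smallest letter; None when no member is annotated."""
    counts = Counter(
        annotations[g] for g in cluster.member_gene_ids if g in annotations
    )
    if not counts:
        return None
    top = max(counts.values())
    return min(c for c, n in counts.items() if n == top)


def unique_clusters(clusters: Sequence[GeneCluster], focal_ids: set[str]) -> list[GeneCluster]:
    """Flag clusters whose member genomes are all focal; returns the input
    list with ``unique_to_focal`` set."""
    for cl in clusters:
        cl.unique_to_focal = bool(cl.member_genome_ids) and cl.member_genome_ids <= focal_ids
    return list(clusters)


def annotate_clusters(clusters: Sequence[GeneCluster], annotations: dict[str, str]) -> list[GeneCluster]:
    for cl in clusters:
        cl.category = assign_cluster_category(cl, annotations)
    return list(clusters)


def functional_composition(
    clusters: Sequence[GeneCluster],
    subset: Optional[Sequence[GeneCluster]] = None,
) -> CompositionTable:
    """Category proportions of the unique subset vs the full pool, among
    annotated clusters only (unannotated excluded from denominators).

    ``subset`` defaults to the clusters flagged ``unique_to_focal``.
    """
    if subset is None:
        subset = [c for c in clusters if c.unique_to_focal]
    table = CompositionTable()
    total_annot = [c for c in clusters if c.category]
    unique_annot = [c for c in subset if c.category]
    table.n_total_annotated = len(total_annot)
    table.n_unique_annotated = len(unique_annot)
    table.annotated_fraction = len(total_annot) / len(clusters) if clusters else 0.0
    if total_annot:
        counts = Counter(c.category for c in total_annot)
        table.total_proportion = {
            c: n / len(total_annot) for c, n in sorted(counts.items())
        }
    if unique_annot:
        counts = Counter(c.category for c in unique_annot)
        table.unique_proportion = {
            c: n / len(unique_annot) for c, n in sorted(counts.items())
        }
    return table


def marker_density_compare(
    genomes: Sequence[GenomeRecord],
    marker_gene_ids: set[str],
    genes: Sequence[GeneRecord],
) -> dict:
    """Per-genome marker-gene density (genes per Mb) compared between focal
    and background groups with a two-sided Mann-Whitney U test."""
    counts: Counter = Counter(
        g.genome_id for g in genes if g.gene_id in marker_gene_ids
    )
    densities: dict[str, list[float]] = {"focal": [], "background": []}
    per_genome: dict[str, float] = {}
    for genome in genomes:
        d = counts.get(genome.genome_id, 0) / (genome.genome_length_bp / 1e6)
        per_genome[genome.genome_id] = d
        key = "focal" if genome.role is Role.FOCAL else "background"
        densities[key].append(d)
    for key, vals in densities.items():
        if len(vals) < 2:
            raise ValueError(f"{key} group has fewer than 2 genomes")
    stat, p = mannwhitneyu(
        densities["focal"], densities["background"], alternative="two-sided"
    )
    return {
        "density_per_genome": per_genome,
        "focal_densities": densities["focal"],
        "background_densities": densities["background"],
        "u_statistic": float(stat),
        "p_value": float(p),
    }
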