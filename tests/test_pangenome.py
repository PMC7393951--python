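"""Ortholog clustering: alignment identity, RBH edges, partition recovery,
majority-rule annotation, unique clusters and composition tables."""

from collections import Counter

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import gotoh_global, identity_of_alignment

from hadalpan.core import GeneRecord, GenomeRecord, Role
from hadalpan.pangenome import (
    GeneCluster,
    annotate_clusters,
    assign_cluster_category,
    build_rbh_graph,
    cluster_genes,
    functional_composition,
    global_protein_identity,
    marker_density_compare,
    unique_clusters,
)


def _gene(gid, genome, category=None):
    return GeneRecord(gid, genome, "c", 1, 9, "+", "ATGTGGTAA", "MW", category)


class TestGlobalProteinIdentity:
    def test_identical_proteins(self):
        ident, _ = global_protein_identity("MKWVTFISLL", "MKWVTFISLL")
        assert ident == 100.0

    def test_matches_dp_oracle_on_classic_pair(self):
        matrix = substitution_matrices.load("BLOSUM62")
        score, aa, bb = gotoh_global("HEAGAWGHEE", "PAWHEAE", matrix)
        ident, impl_score = global_protein_identity("HEAGAWGHEE", "PAWHEAE")
        assert impl_score == pytest.approx(score)
        assert ident == pytest.approx(identity_of_alignment(aa, bb))

    def test_scores_match_oracle_on_random_pairs(self, rng):
        matrix = substitution_matrices.load("BLOSUM62")
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(aas[i] for i in rng.integers(0, 20, size=30))
            b = "".join(aas[i] for i in rng.integers(0, 20, size=25))
            score, _, _ = gotoh_global(a, b, matrix)
            _, impl_score = global_protein_identity(a, b)
            assert impl_score == pytest.approx(score)

    def test_symmetry(self):
        assert global_protein_identity("HEAGAWGHEE", "PAWHEAE")[0] == pytest.approx(
            global_protein_identity("PAWHEAE", "HEAGAWGHEE")[0]
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_protein_identity("", "MKW")


class TestBuildRbhGraph:
    def test_identical_singleton_proteomes_one_edge(self):
        prot = "MKWVTFISLLFLFSSAYSRGV"
        edges = build_rbh_graph({"A": {"a1": prot}, "B": {"b1": prot}})
        assert edges == [("a1", "b1")]

    def test_no_candidate_no_edge(self):
        edges = build_rbh_graph(
            {"A": {"a1": "MKWVTFISLLFLFSSAYSRGV"}, "B": {"b1": "GGGGGGGGGG"}}
        )
        assert edges == []

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            build_rbh_graph({"A": {"a1": "MKW"}})

    def test_planted_families_fully_connected(self, small_clade):
        _, genomes, genes, truth = small_clade
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        edges = set(map(frozenset, build_rbh_graph(proteomes)))
        # every cross-genome pair within a planted family must be connected
        # via the RBH graph (possibly transitively)
        import networkx as nx

        graph = nx.Graph(tuple(e) for e in edges)
        graph.add_nodes_from(g.gene_id for g in genes)
        fams = {}
        for gid, fam in truth.family_of_gene.items():
            fams.setdefault(fam, []).append(gid)
        for fam, members in fams.items():
            if len(members) > 1:
                comp = nx.node_connected_component(graph, members[0])
                assert set(members) <= comp


class TestClusterGenes:
    def test_no_edges_all_singletons(self):
        genes = [_gene(f"g{i}", "A") for i in range(5)]
        clusters = cluster_genes([], genes)
        assert len(clusters) == 5
        assert all(len(c.member_gene_ids) == 1 for c in clusters)

    def test_transitive_closure(self):
        genes = [_gene(g, "A") for g in "abc"]
        clusters = cluster_genes([("a", "b"), ("b", "c")], genes)
        assert len(clusters) == 1
        assert clusters[0].member_gene_ids == {"a", "b", "c"}

    def test_unknown_gene_in_edge_rejected(self):
        with pytest.raises(KeyError):
            cluster_genes([("a", "zz")], [_gene("a", "A")])

    def test_partition_property(self, small_clade):
        _, genomes, genes, truth = small_clade
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        clusters = cluster_genes(build_rbh_graph(proteomes), genes)
        all_members = [gid for c in clusters for gid in c.member_gene_ids]
        assert len(all_members) == len(set(all_members)) == len(genes)

    def test_recovers_planted_families_exactly(self, small_clade):
        _, genomes, genes, truth = small_clade
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        clusters = cluster_genes(build_rbh_graph(proteomes), genes)
        planted = {}
        for gid, fam in truth.family_of_gene.items():
            planted.setdefault(fam, set()).add(gid)
        assert {frozenset(c.member_gene_ids) for c in clusters} == {
            frozenset(v) for v in planted.values()
        }


class TestClusterAnnotation:
    def _cluster(self, members):
        return GeneCluster("GC1", set(members), {"A"})

    def test_majority_wins(self):
        annotations = {"a": "X", "b": "X", "c": "M"}
        assert assign_cluster_category(self._cluster("abc"), annotations) == "X"

    def test_tie_breaks_lexicographically(self):
        annotations = {"a": "M", "b": "X"}
        assert assign_cluster_category(self._cluster("ab"), annotations) == "M"

    def test_all_unannotated(self):
        assert assign_cluster_category(self._cluster("ab"), {}) is None


class TestUniqueClusters:
    def test_mixed_cluster_not_unique(self):
        cl = GeneCluster("GC1", {"a", "b"}, {"F1", "B1"})
        unique_clusters([cl], {"F1", "F2"})
        assert not cl.unique_to_focal

    def test_all_focal_cluster_unique(self):
        cl = GeneCluster("GC1", {"a", "b"}, {"F1", "F2"})
        unique_clusters([cl], {"F1", "F2"})
        assert cl.unique_to_focal

    def test_planted_unique_detection_precision_recall(self, small_clade):
        _, genomes, genes, truth = small_clade
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        clusters = cluster_genes(build_rbh_graph(proteomes), genes)
        focal = {g.genome_id for g in genomes if g.role is Role.FOCAL}
        unique_clusters(clusters, focal)
        predicted = {gid for c in clusters if c.unique_to_focal for gid in c.member_gene_ids}
        tp = len(predicted & truth.unique_gene_ids)
        assert tp / len(predicted) >= 0.9
        assert tp / len(truth.unique_gene_ids) >= 0.9


class TestFunctionalComposition:
    def _clusters(self, cats, unique_flags):
        out = []
        for i, (c, u) in enumerate(zip(cats, unique_flags)):
            cl = GeneCluster(f"GC{i}", {f"g{i}"}, {"F1"}, category=c, unique_to_focal=u)
            out.append(cl)
        return out

    def test_unique_proportions(self):
        clusters = self._clusters(["X", "X", "M"], [True, True, True])
        t = functional_composition(clusters)
        assert t.unique_proportion == {"M": pytest.approx(1 / 3), "X": pytest.approx(2 / 3)}

    def test_unannotated_excluded_from_denominator(self):
        clusters = self._clusters(["X", "M", "K", None], [False] * 4)
        t = functional_composition(clusters)
        assert t.total_proportion == {
            "K": pytest.approx(1 / 3),
            "M": pytest.approx(1 / 3),
            "X": pytest.approx(1 / 3),
        }
        assert t.annotated_fraction == pytest.approx(0.75)

    def test_proportions_sum_to_one(self, small_clade):
        _, genomes, genes, truth = small_clade
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        clusters = cluster_genes(build_rbh_graph(proteomes), genes)
        annotations = {g.gene_id: g.category for g in genes if g.category}
        annotate_clusters(clusters, annotations)
        focal = {g.genome_id for g in genomes if g.role is Role.FOCAL}
        unique_clusters(clusters, focal)
        t = functional_composition(clusters)
        assert sum(t.unique_proportion.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(t.total_proportion.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_enrichment_recovered(self, small_clade):
        """Category X is over-weighted among planted unique genes, so its
        unique-pool proportion exceeds its total-pool proportion."""
        _, genomes, genes, truth = small_clade
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        clusters = cluster_genes(build_rbh_graph(proteomes), genes)
        annotations = {g.gene_id: g.category for g in genes if g.category}
        annotate_clusters(clusters, annotations)
        focal = {g.genome_id for g in genomes if g.role is Role.FOCAL}
        unique_clusters(clusters, focal)
        t = functional_composition(clusters)
        assert t.unique_proportion.get("X", 0) > t.total_proportion.get("X", 0)

    def test_empty_input(self):
        t = functional_composition([])
        assert t.total_proportion == {} and t.n_total_annotated == 0


class TestMarkerDensity:
    def _genomes(self, rng, n_focal, n_background, lengths=None):
        out = []
        for i in range(n_focal + n_background):
            n = 10000 if lengths is None else lengths[i]
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
            role = Role.FOCAL if i < n_focal else Role.BACKGROUND
            out.append(GenomeRecord(f"g{i}", [("c", seq)], role=role))
        return out

    def test_identical_densities_maximal_p(self, rng):
        genomes = self._genomes(rng, 2, 2)
        genes = [_gene(f"m{i}", g.genome_id) for i, g in enumerate(genomes)]
        res = marker_density_compare(genomes, {g.gene_id for g in genes}, genes)
        assert res["p_value"] == pytest.approx(1.0)

    def test_single_genome_group_rejected(self, rng):
        genomes = self._genomes(rng, 1, 2)
        with pytest.raises(ValueError):
            marker_density_compare(genomes, set(), [])

    def test_type_one_error_rate(self):
        """Densities drawn from the same distribution: rejection rate at
        alpha = 0.05 stays near nominal over 1000 simulated datasets."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sets = 1000
        for _ in range(n_sets):
            # lengths redrawn per dataset so a one-off length imbalance
            # between groups cannot masquerade as a persistent signal;
            # only the lengths matter for density, so use constant bases
            genomes = [
                GenomeRecord(
                    f"g{i}",
                    [("c", "A" * int(n))],
                    role=Role.FOCAL if i < 10 else Role.BACKGROUND,
                )
                for i, n in enumerate(rng.integers(8000, 12000, size=20))
            ]
            genes = []
            k = 0
            for g in genomes:
                for _ in range(int(rng.poisson(25))):
                    genes.append(_gene(f"m{k}", g.genome_id))
                    k += 1
            res = marker_density_compare(genomes, {g.gene_id for g in genes}, genes)
            rejections += res["p_value"] < 0.05
        assert 0.03 <= rejections / n_sets <= 0.07
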