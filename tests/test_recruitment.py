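"""Read recruitment: tabular parsing, threshold filters, competitive
assignment, the built-in mapper, RPKG and profile clustering."""

import numpy as np
import pytest

from oracles import competitive_assign_oracle, complete_linkage_heights

from hadalpan.core import GenomeRecord, reverse_complement
from hadalpan.recruitment import (
    RecruitmentHit,
    cluster_profiles,
    competitive_assign,
    filter_hits,
    map_reads_simple,
    parse_blast_tab,
    rpkg,
    rpkg_matrix,
    znormalize,
)
from hadalpan.simulate import CladeConfig, simulate_clade, simulate_reads


def _hit(read="r1", genome="g1", ident=99.0, cov=100.0, score=200.0, ev=1e-30):
    return RecruitmentHit(read, genome, ident, cov, 150, score, ev)


class TestParseBlastTab:
    LINE = "r1\tc1\t97.33\t150\t4\t0\t1\t150\t1001\t1150\t1e-70\t271.0\n"

    def _parse(self, tmp_path, text, read_lengths=None, contig_map=None):
        p = tmp_path / "hits.tsv"
        p.write_text(text)
        return parse_blast_tab(
            p,
            read_lengths if read_lengths is not None else {"r1": 150},
            contig_map if contig_map is not None else {"c1": "g1"},
        )

    def test_parses_fields(self, tmp_path):
        (h,) = self._parse(tmp_path, self.LINE)
        assert h.read_id == "r1" and h.genome_id == "g1"
        assert h.percent_identity == 97.33
        assert h.query_coverage_percent == pytest.approx(100.0)
        assert h.evalue == 1e-70 and h.score == 271.0

    def test_reversed_query_span_coverage(self, tmp_path):
        line = "r1\tc1\t97.0\t120\t4\t0\t140\t21\t1001\t1120\t1e-50\t200.0\n"
        (h,) = self._parse(tmp_path, line)
        assert h.query_coverage_percent == pytest.approx(100.0 * 120 / 150)

    def test_blank_lines_skipped(self, tmp_path):
        assert len(self._parse(tmp_path, "\n" + self.LINE + "\n")) == 1

    def test_wrong_column_count_names_line(self, tmp_path):
        with pytest.raises(ValueError, match="line 2"):
            self._parse(tmp_path, self.LINE + "r1\tc1\tbroken\n")

    def test_non_numeric_field_names_line(self, tmp_path):
        bad = self.LINE.replace("97.33", "NA")
        with pytest.raises(ValueError, match="line 1"):
            self._parse(tmp_path, bad)

    def test_unknown_contig_rejected(self, tmp_path):
        with pytest.raises(KeyError, match="c1"):
            self._parse(tmp_path, self.LINE, contig_map={"other": "g1"})

    def test_unknown_read_rejected(self, tmp_path):
        with pytest.raises(KeyError, match="r1"):
            self._parse(tmp_path, self.LINE, read_lengths={"other": 150})


class TestFilterHits:
    def test_identity_boundary_inclusive(self):
        kept = filter_hits([_hit(ident=95.0), _hit(ident=94.9)])
        assert [h.percent_identity for h in kept] == [95.0]

    def test_coverage_boundary_inclusive(self):
        kept = filter_hits([_hit(cov=80.0), _hit(cov=79.9)])
        assert [h.query_coverage_percent for h in kept] == [80.0]

    def test_evalue_boundary_inclusive(self):
        kept = filter_hits([_hit(ev=1e-5), _hit(ev=2e-5)])
        assert [h.evalue for h in kept] == [1e-5]

    def test_missing_evalue_passes(self):
        assert len(filter_hits([_hit(ev=None)])) == 1


class TestCompetitiveAssign:
    def test_highest_identity_wins(self):
        hits = [_hit(genome="g1", ident=96.0), _hit(genome="g2", ident=99.0)]
        assert competitive_assign(hits) == {"r1": "g2"}

    def test_identity_tie_broken_by_score(self):
        hits = [
            _hit(genome="g1", ident=99.0, score=100.0),
            _hit(genome="g2", ident=99.0, score=150.0),
        ]
        assert competitive_assign(hits) == {"r1": "g2"}

    def test_full_tie_broken_lexicographically(self):
        hits = [_hit(genome="gB"), _hit(genome="gA"), _hit(genome="gC")]
        assert competitive_assign(hits) == {"r1": "gA"}

    def test_prefix_genome_ids_tie(self):
        # 'g' < 'g10' lexicographically; prefix ids must not invert the rule
        hits = [_hit(genome="g10"), _hit(genome="g")]
        assert competitive_assign(hits) == {"r1": "g"}

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        genomes = ["g", "g1", "g10", "a", "zz"]
        for _ in range(1000):
            hits = []
            for _ in range(int(rng.integers(1, 12))):
                hits.append(
                    _hit(
                        read=f"r{rng.integers(0, 4)}",
                        genome=genomes[rng.integers(0, len(genomes))],
                        ident=float(rng.choice([95.0, 97.5, 99.0])),
                        score=float(rng.choice([100.0, 150.0])),
                    )
                )
            assert competitive_assign(hits) == competitive_assign_oracle(hits)


@pytest.fixture(scope="module")
def pair():
    cfg = CladeConfig(
        n_focal=1,
        n_background=1,
        n_core_genes=20,
        gene_length_codons=(150, 250),
        ani_targets=[0.0, 0.12],
        unique_genes_per_focal=0,
        seed=4,
    )
    genomes, _, _ = simulate_clade(cfg)
    return genomes


class TestMapReadsSimple:
    def test_error_free_reads_map_to_origin_perfectly(self, pair):
        reads, origin = simulate_reads(pair, [1.0, 0.0], 50, seed=1)
        hits = map_reads_simple(reads, pair)
        assigned = competitive_assign(hits)
        for rid, _ in reads:
            assert assigned[rid] == origin[rid][0]
        perfect = [h for h in hits if h.genome_id == pair[0].genome_id]
        assert all(h.percent_identity == 100.0 for h in perfect)

    def test_minus_strand_read_maps(self, pair):
        seq = pair[0].contigs[0][1][100:250]
        hits = map_reads_simple([("rc", reverse_complement(seq))], [pair[0]])
        assert len(hits) == 1 and hits[0].percent_identity == 100.0

    def test_foreign_read_unmapped(self, pair):
        rng = np.random.default_rng(0)
        # P(a random 150-mer shares a specific 21-mer with a ~50 kb
        # genome, both strands) ~ 130 * 2 * 5e4 / 4^21 < 1e-5
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        assert map_reads_simple([("x", read)], [pair[0]]) == []

    def test_identity_counts_substitutions(self, pair):
        seq = pair[0].contigs[0][1][0:150]
        mutated = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        (h,) = map_reads_simple([("m", mutated)], [pair[0]])
        assert h.percent_identity == pytest.approx(100.0 * 149 / 150)


class TestRpkg:
    def test_worked_example(self):
        # 1000 reads, 2 Mb genome, 1 Gb metagenome:
        # (1000 / 1 Gb) / 2000 kb = 0.5
        assert rpkg(1000, 2_000_000, 1_000_000_000) == pytest.approx(0.5)

    def test_linear_in_reads(self):
        assert rpkg(500, 10 ** 6, 10 ** 9) == pytest.approx(
            0.5 * rpkg(1000, 10 ** 6, 10 ** 9)
        )

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            rpkg(10, 0, 10 ** 9)

    def test_matrix_layout(self):
        genomes = [
            GenomeRecord("g1", [("c", "A" * 1000)]),
            GenomeRecord("g2", [("c", "A" * 2000)]),
        ]
        counts = {"s1": {"g1": 10, "g2": 10}, "s2": {"g1": 4}}
        mat, gids, sids = rpkg_matrix(counts, genomes, {"s1": 10 ** 6, "s2": 10 ** 6})
        assert gids == ["g1", "g2"] and sids == ["s1", "s2"]
        assert mat[0, 0] == pytest.approx(rpkg(10, 1000, 10 ** 6))
        assert mat[1, 1] == 0.0
        # equal reads, double length -> half the RPKG
        assert mat[1, 0] == pytest.approx(mat[0, 0] / 2)


class TestZnormalize:
    def test_known_row_sample_sd(self):
        out = znormalize(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 0.0, 1.0]])  # sd with ddof=1 is 1

    def test_constant_row_maps_to_zeros(self):
        out = znormalize(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert np.allclose(out[0], 0.0)

    def test_rows_have_zero_mean_unit_sd(self, rng):
        out = znormalize(rng.normal(size=(4, 6)))
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            znormalize(np.array([[1.0], [2.0]]))


class TestClusterProfiles:
    def test_heights_match_naive_oracle(self, rng):
        mat = rng.normal(size=(6, 4))
        ids = [f"g{i}" for i in range(6)]
        link, _, _ = cluster_profiles(mat, ids)
        assert np.allclose(sorted(link[:, 2]), complete_linkage_heights(mat))

    def test_outlier_joins_last(self, rng):
        mat = np.vstack([rng.normal(size=(4, 5)) * 0.01, np.full((1, 5), 50.0)])
        ids = ["a", "b", "c", "d", "outlier"]
        link, leaf_order, newick = cluster_profiles(mat, ids)
        # the outlier is alone on one side of the root split
        assert leaf_order[0] == "outlier" or leaf_order[-1] == "outlier"

    def test_newick_contains_all_leaves_once(self, rng):
        mat = rng.normal(size=(5, 4))
        ids = [f"g{i}" for i in range(5)]
        _, _, newick = cluster_profiles(mat, ids)
        assert newick.endswith(";")
        for gid in ids:
            assert newick.count(gid) == 1
        assert newick.count("(") == newick.count(")") == 4

    def test_row_order_does_not_matter(self, rng):
        mat = rng.normal(size=(5, 4))
        ids = [f"g{i}" for i in range(5)]
        perm = [3, 0, 4, 1, 2]
        _, _, n1 = cluster_profiles(mat, ids)
        _, _, n2 = cluster_profiles(mat[perm], [ids[i] for i in perm])
        assert n1 == n2

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(np.ones((1, 3)), ["g"])
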