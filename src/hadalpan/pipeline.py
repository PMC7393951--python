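"""End-to-end orchestration: simulate a clade, then run ANI-based relative
selection, pangenome clustering, variation deciles, codon usage and read
recruitment, writing every stage's tables plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from ._align import ProteinSet
from .ani import ani_matrix, select_close_relatives
from .codon import enc_comparison, enc_for_gene
from .core import GeneRecord, GenomeRecord, Role, SampleMeta, SizeFraction
from .pangenome import (
    annotate_clusters,
    build_rbh_graph,
    cluster_genes,
    functional_composition,
    unique_clusters,
)
from .recruitment import (
    cluster_profiles,
    competitive_assign,
    filter_hits,
    map_reads_simple,
    rpkg_matrix,
    znormalize,
)
from .seqio import write_annotation_table, write_fasta, write_gene_table, write_sample_table
from .simulate import (
    CladeConfig,
    depth_structured_abundances,
    simulate_clade,
    simulate_reads,
)
from .variation import (
    VariationRecord,
    category_bin_profile,
    category_correlation,
    rank_into_bins,
    top_hit_identity,
)

__all__ = ["PipelineConfig", "run_all", "load_config"]

DEFAULT_DEPTHS = (0.0, 4000.0, 9600.0, 10400.0, 10500.0)


@dataclass
class PipelineConfig:
    """Thresholds and stage parameters; the defaults are the standard
    values of the analysis (ANI > 95, identity >= 95, coverage >= 80,
    evalue <= 1e-5, ten bins, p < 0.01)."""

    seed: Optional[int] = None
    ani_threshold: float = 95.0
    recruit_min_identity: float = 95.0
    recruit_min_coverage: float = 80.0
    recruit_max_evalue: float = 1e-5
    n_bins: int = 10
    p_cutoff: float = 0.01
    variation_min_score: float = 50.0
    reads_per_sample: int = 3000
    read_length_bp: int = 150
    read_error_rate: float = 0.005
    depths_m: tuple[float, ...] = DEFAULT_DEPTHS
    sim: CladeConfig = field(default_factory=CladeConfig)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required when simulation is enabled")
        if not 0 < self.ani_threshold < 100:
            raise ValueError("ani_threshold out of range")
        if not 0 <= self.recruit_min_identity <= 100:
            raise ValueError("recruit_min_identity out of range")
        if not 0 <= self.recruit_min_coverage <= 100:
            raise ValueError("recruit_min_coverage out of range")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff out of range")


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = CladeConfig(**raw.pop("sim", {}))
    if "depths_m" in raw:
        raw["depths_m"] = tuple(raw["depths_m"])
    if "gene_length_codons" in asdict(sim):
        sim.gene_length_codons = tuple(sim.gene_length_codons)
    cfg = PipelineConfig(sim=sim, **raw)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated clade; returns a summary dict and
    writes all tables plus ``manifest.json`` under ``outdir``."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed
    rng = np.random.default_rng(config.seed + 1)

    # --- simulate
    genomes, genes, truth = simulate_clade(config.sim)
    gdir = out / "genomes"
    gdir.mkdir(exist_ok=True)
    for g in genomes:
        write_fasta(gdir / f"{g.genome_id}.fna", g.contigs)
    write_fasta(out / "cds.fna", [(g.gene_id, g.cds) for g in genes])
    write_fasta(out / "proteins.faa", [(g.gene_id, g.protein) for g in genes])
    write_gene_table(out / "genes.tsv", genes)
    write_annotation_table(
        out / "annotations.tsv", {g.gene_id: g.category for g in genes if g.category}
    )

    samples = [
        SampleMeta(
            sample_id=f"S{i + 1:02d}_{int(d)}m",
            depth_m=d,
            size_fraction=SizeFraction.FREE_LIVING,
            metagenome_size_bp=config.reads_per_sample * config.read_length_bp,
        )
        for i, d in enumerate(config.depths_m)
    ]
    write_sample_table(out / "samples.tsv", samples)
    abundance = depth_structured_abundances(
        [g.genome_id for g in genomes], [s.depth_m for s in samples], rng
    )
    truth.abundance = abundance
    truth.sample_ids = [s.sample_id for s in samples]
    np.savetxt(out / "truth_abundance.tsv", abundance, delimiter="\t", fmt="%.6g")

    # --- ANI and relative selection
    results = ani_matrix(genomes)
    with open(out / "ani.tsv", "w", encoding="utf-8") as fh:
        fh.write("genome_a\tgenome_b\tani_percent\tn_fragments_used\tcoverage_fraction\n")
        seen = set()
        for (a, b), res in sorted(results.items()):
            if (b, a) in seen:
                continue
            seen.add((a, b))
            ani_str = "NA" if res.ani_percent is None else f"{res.ani_percent:.3f}"
            fh.write(f"{a}\t{b}\t{ani_str}\t{res.n_fragments_used}\t{res.coverage_fraction:.3f}\n")
    focal_ids = [g.genome_id for g in genomes if g.role is Role.FOCAL]
    background_ids = [g.genome_id for g in genomes if g.role is Role.BACKGROUND]
    relatives = select_close_relatives(
        results, focal_ids, background_ids, threshold=config.ani_threshold
    )
    (out / "close_relatives.txt").write_text("\n".join(sorted(relatives)) + "\n")

    # --- pangenome (focal + selected relatives)
    keep = set(focal_ids) | relatives
    pan_genes = [g for g in genes if g.genome_id in keep]
    proteomes: dict[str, dict[str, str]] = {}
    for g in pan_genes:
        proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
    annotations = {g.gene_id: g.category for g in pan_genes if g.category}
    edges = build_rbh_graph(proteomes)
    clusters = cluster_genes(edges, pan_genes)
    annotate_clusters(clusters, annotations)
    unique_clusters(clusters, set(focal_ids))
    with open(out / "clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("cluster_id\tgene_id\tgenome_id\tcategory\tunique_to_focal\n")
        genome_of = {g.gene_id: g.genome_id for g in pan_genes}
        for cl in clusters:
            for gid in sorted(cl.member_gene_ids):
                fh.write(
                    f"{cl.cluster_id}\t{gid}\t{genome_of[gid]}\t{cl.category or ''}\t"
                    f"{int(cl.unique_to_focal)}\n"
                )
    composition = functional_composition(clusters)
    with open(out / "composition.tsv", "w", encoding="utf-8") as fh:
        fh.write("category\tunique_proportion\ttotal_proportion\n")
        cats = sorted(set(composition.unique_proportion) | set(composition.total_proportion))
        for c in cats:
            fh.write(
                f"{c}\t{composition.unique_proportion.get(c, 0.0):.6f}\t"
                f"{composition.total_proportion.get(c, 0.0):.6f}\n"
            )

    # --- variation deciles (focal annotated genes vs background proteomes)
    background_prots = {
        gid: prot
        for genome_id in relatives
        for gid, prot in proteomes.get(genome_id, {}).items()
    }
    summary_variation = {}
    correlations = []
    if background_prots:
        background_set = ProteinSet(background_prots)
        records = []
        for g in pan_genes:
            if g.genome_id in focal_ids and g.category:
                ident = top_hit_identity(
                    g.protein, background_set, min_score=config.variation_min_score
                )
                records.append(VariationRecord(g.gene_id, g.category, ident))
        usable = [r for r in records if r.top_hit_identity is not None]
        if len(usable) >= config.n_bins:
            binned = rank_into_bins(records, n_bins=config.n_bins)
            profile, mean_diss = category_bin_profile(binned, n_bins=config.n_bins)
            correlations = category_correlation(profile, mean_diss, p_cutoff=config.p_cutoff)
            with open(out / "variation_records.tsv", "w", encoding="utf-8") as fh:
                fh.write("gene_id\tcategory\ttop_hit_identity\tdissimilarity\tbin\n")
                for r in binned:
                    fh.write(
                        f"{r.gene_id}\t{r.category}\t{r.top_hit_identity:.3f}\t"
                        f"{r.dissimilarity:.3f}\t{r.bin_index}\n"
                    )
            with open(out / "variation_correlations.tsv", "w", encoding="utf-8") as fh:
                fh.write("category\tpearson_r\tp_value\tsignificant\n")
                for c in correlations:
                    r_str = "NA" if c.pearson_r is None else f"{c.pearson_r:.6f}"
                    p_str = "NA" if c.p_value is None else f"{c.p_value:.3g}"
                    fh.write(f"{c.category}\t{r_str}\t{p_str}\t{int(c.significant)}\n")
            summary_variation = {
                "n_binned": len(binned),
                "significant_categories": [
                    c.category for c in correlations if c.significant and (c.pearson_r or 0) > 0
                ],
            }

    # --- codon usage
    unique_gene_ids = {
        gid for cl in clusters if cl.unique_to_focal for gid in cl.member_gene_ids
    }
    with open(out / "codon_usage.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcategory\tenc\tgc3\texpected_enc\tbelow_curve\n")
        for g in pan_genes:
            r = enc_for_gene(g)
            enc_str = "NA" if r.enc is None else f"{r.enc:.3f}"
            gc3_str = "NA" if r.gc3 is None else f"{r.gc3:.4f}"
            exp_str = "NA" if r.expected_enc_at_gc3 is None else f"{r.expected_enc_at_gc3:.3f}"
            below = "NA" if r.below_curve is None else str(int(r.below_curve))
            fh.write(f"{g.gene_id}\t{g.category or ''}\t{enc_str}\t{gc3_str}\t{exp_str}\t{below}\n")
    unique_genes = [g for g in pan_genes if g.gene_id in unique_gene_ids]
    codon_summary = None
    if unique_genes:
        codon_summary = enc_comparison(unique_genes, pan_genes)

    # --- recruitment
    counts: dict[str, dict[str, int]] = {}
    for j, sample in enumerate(samples):
        reads, origin = simulate_reads(
            genomes,
            abundance[:, j],
            n_reads=config.reads_per_sample,
            read_length_bp=config.read_length_bp,
            error_rate=config.read_error_rate,
            seed=config.seed + 100 + j,
        )
        truth.read_origin.update({f"{sample.sample_id}:{rid}": o for rid, o in origin.items()})
        write_fasta(out / f"reads_{sample.sample_id}.fna", reads)
        hits = map_reads_simple(reads, genomes)
        hits = filter_hits(
            hits,
            max_evalue=config.recruit_max_evalue,
            min_identity=config.recruit_min_identity,
            min_coverage=config.recruit_min_coverage,
        )
        assignment = competitive_assign(hits)
        per_genome: dict[str, int] = {}
        for gid in assignment.values():
            per_genome[gid] = per_genome.get(gid, 0) + 1
        counts[sample.sample_id] = per_genome
    mat, genome_order, sample_order = rpkg_matrix(
        counts,
        genomes,
        {s.sample_id: s.metagenome_size_bp for s in samples},
        sample_order=[s.sample_id for s in samples],
    )
    _write_matrix(out / "rpkg.tsv", mat, genome_order, sample_order)
    z = znormalize(mat)
    _write_matrix(out / "rpkg_z.tsv", z, genome_order, sample_order)
    _, leaf_order, newick = cluster_profiles(z, genome_order)
    (out / "profiles.nwk").write_text(newick + "\n")

    # --- manifest
    manifest = {
        "hadalpan_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {
            "ani_threshold": config.ani_threshold,
            "recruit_min_identity": config.recruit_min_identity,
            "recruit_min_coverage": config.recruit_min_coverage,
            "recruit_max_evalue": config.recruit_max_evalue,
            "n_bins": config.n_bins,
            "p_cutoff": config.p_cutoff,
            "variation_min_score": config.variation_min_score,
        },
        "sim": asdict(config.sim),
        "input_checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    manifest_json = json.dumps(manifest, indent=2, default=str)
    (out / "manifest.json").write_text(manifest_json)
    manifest_hash = hashlib.sha256(manifest_json.encode()).hexdigest()

    return {
        "genomes": [g.genome_id for g in genomes],
        "close_relatives": sorted(relatives),
        "n_clusters": len(clusters),
        "n_unique_clusters": sum(c.unique_to_focal for c in clusters),
        "composition": composition,
        "variation": summary_variation,
        "correlations": correlations,
        "codon": codon_summary,
        "rpkg": mat,
        "leaf_order": leaf_order,
        "manifest_hash": manifest_hash,
        "truth": truth,
    }


def _write_matrix(path, mat, row_ids, col_ids) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\t" + "\t".join(col_ids) + "\n")
        for i, rid in enumerate(row_ids):
            fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in mat[i]) + "\n")
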