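"""Fragment recruitment, RPKG abundance and depth-profile clustering.

Reads simulated from a community with known genome abundances are mapped
back competitively (each read to its highest-identity genome), filtered
at >= 95% identity and >= 80% coverage, and converted to RPKG -- reads
per kilobase of genome per gigabase of metagenome.  Z-normalised depth
profiles are then clustered (complete linkage) into a Newick tree.
"""

import numpy as np

from hadalpan.recruitment import (
    cluster_profiles,
    competitive_assign,
    filter_hits,
    map_reads_simple,
    rpkg_matrix,
    znormalize,
)
from hadalpan.simulate import CladeConfig, depth_structured_abundances, simulate_clade, simulate_reads

config = CladeConfig(
    n_focal=1,
    n_background=3,
    n_core_genes=60,
    ani_targets=[0.0, 0.06, 0.12, 0.18],
    unique_genes_per_focal=0,
    seed=29,
)
genomes, _, _ = simulate_clade(config)
genome_ids = [g.genome_id for g in genomes]

depths = [0.0, 2000.0, 6000.0, 10500.0]
rng = np.random.default_rng(29)
abundance = depth_structured_abundances(genome_ids, depths, rng)

counts = {}
n_reads, read_len = 4000, 150
for j, depth in enumerate(depths):
    reads, _ = simulate_reads(
        genomes, abundance[:, j], n_reads, read_length_bp=read_len,
        error_rate=0.005, seed=100 + j,
    )
    hits = filter_hits(map_reads_simple(reads, genomes))
    assignment = competitive_assign(hits)
    per_genome = {}
    for gid in assignment.values():
        per_genome[gid] = per_genome.get(gid, 0) + 1
    counts[f"{int(depth)}m"] = per_genome

mat, gids, samples = rpkg_matrix(
    counts, genomes, {s: n_reads * read_len for s in counts}, sample_order=list(counts)
)
print("RPKG (genome x sample):")
print("          " + "  ".join(f"{s:>8}" for s in samples))
for i, gid in enumerate(gids):
    print(f"  {gid}   " + "  ".join(f"{v:8.1f}" for v in mat[i]))

print("\nplanted relative abundance for comparison:")
for i, gid in enumerate(genome_ids):
    print(f"  {gid}   " + "  ".join(f"{v:8.3f}" for v in abundance[i]))

_, leaf_order, newick = cluster_profiles(znormalize(mat), gids)
print(f"\ndepth-profile dendrogram: {newick}")
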