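"""Simulate a small clade with planted ground truth.

Two focal genomes and two background relatives descend from a common
ancestor; each genome carries a planted nucleotide divergence, and each
focal genome receives a handful of genes no other genome has.  The
returned truth object records every planted quantity, which is what the
rest of the examples recover.
"""

from collections import Counter

from hadalpan.simulate import CladeConfig, simulate_clade

config = CladeConfig(
    n_focal=2,
    n_background=2,
    n_core_genes=80,
    ani_targets=[0.01, 0.01, 0.02, 0.08],  # divergence from the ancestor
    unique_genes_per_focal=8,
    seed=7,
)
genomes, genes, truth = simulate_clade(config)

print("genome sizes:")
for g in genomes:
    n_genes = sum(1 for x in genes if x.genome_id == g.genome_id)
    print(f"  {g.genome_id} ({g.role.value:10s}) {g.genome_length_bp:7,} bp, {n_genes} genes")

print("\nplanted nucleotide divergence from the ancestor:")
for gid, d in truth.planted_nt_divergence.items():
    print(f"  {gid}: {d:.4f}")

unique_by_genome = Counter(
    next(x.genome_id for x in genes if x.gene_id == uid) for uid in truth.unique_gene_ids
)
print(f"\nplanted focal-only genes: {dict(sorted(unique_by_genome.items()))}")
cats = Counter(x.category for x in genes if x.gene_id in truth.unique_gene_ids)
print(f"their functional categories: {dict(sorted(cats.items()))}")
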