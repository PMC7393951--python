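"""Fragment-based ANI and the strict >95% relative-selection rule.

Genomes are cut into 1 kb windows; each window is aligned (ungapped,
seeded by exact 15-mers on both strands) against the other genome and
accepted when at least 70% aligns at >= 30% identity.  ANI is the mean
identity of accepted windows, symmetrised.  Background genomes are kept
as "close relatives" only when ANI to some focal genome exceeds 95%.
"""

from hadalpan.ani import ani_matrix, select_close_relatives
from hadalpan.core import Role
from hadalpan.simulate import CladeConfig, simulate_clade

config = CladeConfig(
    n_focal=1,
    n_background=3,
    n_core_genes=60,
    ani_targets=[0.0, 0.01, 0.02, 0.10],
    unique_genes_per_focal=0,  # substitution-only pairs: ANI is exactly interpretable
    seed=11,
)
genomes, _, truth = simulate_clade(config)

results = ani_matrix(genomes)
print("pairwise ANI (percent):")
seen = set()
for (a, b), res in sorted(results.items()):
    if (b, a) in seen:
        continue
    seen.add((a, b))
    print(f"  {a} vs {b}: {res.ani_percent:6.2f}  ({res.n_fragments_used} fragments)")

focal = [g.genome_id for g in genomes if g.role is Role.FOCAL]
background = [g.genome_id for g in genomes if g.role is Role.BACKGROUND]
relatives = select_close_relatives(results, focal, background)
print(f"\nbackground genomes with ANI > 95% to a focal genome: {sorted(relatives)}")
print("(planted divergences from the ancestor:",
      {k: f"{v:.3f}" for k, v in truth.planted_nt_divergence.items()}, ")")
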