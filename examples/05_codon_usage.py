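"""Wright's effective number of codons (ENC) against GC3.

ENC runs from 20 (one codon per amino acid, maximal bias) to 61 (all
synonymous codons used equally).  Genes below the expected ENC-GC3 curve
use fewer codons than their GC content alone explains, the classic
signature of selection on codon usage.  The generator's bias knob moves
genes from the curve (0.0) down toward the floor (1.0).
"""

import numpy as np

from hadalpan.codon import count_codons, enc, expected_enc, gc3
from hadalpan.simulate import generate_gene

rng = np.random.default_rng(23)

print("bias   mean ENC   mean GC3   expected ENC at that GC3")
for strength in (0.0, 0.3, 0.6, 1.0):
    encs, gc3s = [], []
    for _ in range(40):
        cds = generate_gene(rng, 300, strength)
        encs.append(enc(count_codons(cds)))
        gc3s.append(gc3(cds))
    e, g = np.mean(encs), np.mean(gc3s)
    print(f" {strength:.1f}     {e:5.2f}      {g:.3f}          {expected_enc(g):5.2f}")

print("\nanalytic end points:")
one_per_family = enc(count_codons(
    "GCT" * 5 + "TGT" * 5 + "GAT" * 5 + "GAA" * 5 + "TTT" * 5 + "GGT" * 5
    + "CAT" * 5 + "ATT" * 5 + "AAA" * 5 + "CTT" * 5 + "AAT" * 5 + "CCT" * 5
    + "CAA" * 5 + "CGT" * 5 + "TCT" * 5 + "ACT" * 5 + "GTT" * 5 + "TAT" * 5 + "TAA"
))
print(f"  one codon per amino acid -> ENC = {one_per_family}")
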