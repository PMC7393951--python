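"""Codon-usage bias statistics: Wright's effective number of codons (ENC),
GC3, and the expected ENC-GC3 curve under random (mutation-driven) codon
usage.

ENC ranges from 20 (maximal bias: one codon used exclusively per amino
acid) to 61 (no bias: synonymous codons used equally often).  Genes lying
below the expected curve show selection on codon usage beyond what their
GC3 alone would produce.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import CODON_TO_AA, STOP_CODONS, GeneRecord

__all__ = [
    "CodonCounts",
    "EncResult",
    "count_codons",
    "family_homozygosity",
    "enc",
    "gc3",
    "expected_enc",
    "enc_for_gene",
    "enc_comparison",
    "SYNONYMOUS_FAMILIES",
    "DEGENERACY_CLASSES",
]

#: amino acid -> tuple of synonymous codons (stop codons excluded).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: degeneracy class -> amino acids.  Met and Trp (single-codon families)
#: carry no information about synonymous choice and are excluded from ENC.
#: The three 6-fold families (Leu, Ser, Arg) are treated as single 6-fold
#: families rather than 2+4 subfamilies.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    2: tuple(sorted(a for a, c in SYNONYMOUS_FAMILIES.items() if len(c) == 2)),
    3: ("I",),
    4: tuple(sorted(a for a, c in SYNONYMOUS_FAMILIES.items() if len(c) == 4)),
    6: tuple(sorted(a for a, c in SYNONYMOUS_FAMILIES.items() if len(c) == 6)),
}
assert len(DEGENERACY_CLASSES[2]) == 9 and len(DEGENERACY_CLASSES[4]) == 5

#: class weights in Wright's formula: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
_CLASS_SIZE = {2: 9, 3: 1, 4: 5, 6: 3}

ENC_MIN = 20.0
ENC_MAX = 61.0


@dataclass
class CodonCounts:
    """Synonymous-codon counts keyed by amino-acid family.

    Single-codon families (Met, Trp) and stop codons are never counted;
    codons containing a base outside A/C/G/T are skipped.
    """

    by_family: dict[str, Counter]

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.by_family.values())


def count_codons(cds: str) -> CodonCounts:
    """Count synonymous codon usage of one CDS.

    The trailing stop codon is excluded; an internal stop is an error.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    by_family: dict[str, Counter] = {}
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon at codon position {i + 1}")
        aa = CODON_TO_AA.get(codon)
        if aa is None:  # ambiguous base somewhere in the codon
            continue
        if len(SYNONYMOUS_FAMILIES[aa]) == 1:  # Met, Trp
            continue
        by_family.setdefault(aa, Counter())[codon] += 1
    return CodonCounts(by_family)


def family_homozygosity(counts: Counter) -> Optional[float]:
    """Wright's codon homozygosity F-hat for one amino-acid family.

    F = (n * sum(p_i^2) - 1) / (n - 1) with p_i the within-family codon
    frequencies.  Undefined (None) when fewer than two codons were observed
    or when the estimate is non-positive.
    """
    n = sum(counts.values())
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc(counts: CodonCounts) -> Optional[float]:
    """Wright's effective number of codons for one gene's codon counts.

    Class means of F-hat are taken over families where it is defined; a
    missing 3-fold class is imputed as the mean of the 2- and 4-fold class
    averages; any other missing class makes ENC undefined.  Raw values
    above 61 (a finite-sample artifact of perfectly even usage) are
    truncated to 61.
    """
    class_mean: dict[int, Optional[float]] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            fam = counts.by_family.get(aa)
            if fam:
                f = family_homozygosity(fam)
                if f is not None:
                    fs.append(f)
        class_mean[k] = sum(fs) / len(fs) if fs else None

    if class_mean[3] is None:
        if class_mean[2] is None or class_mean[4] is None:
            return None
        class_mean[3] = (class_mean[2] + class_mean[4]) / 2.0
    for k in (2, 4, 6):
        if class_mean[k] is None:
            return None

    value = 2.0 + sum(_CLASS_SIZE[k] / class_mean[k] for k in (2, 3, 4, 6))
    return min(value, ENC_MAX)


def gc3(cds: str) -> Optional[float]:
    """Fraction of G or C at the third position of sense codons.

    Trailing stop excluded; codons with an ambiguous third base skipped.
    Undefined (None) when no codon is countable.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    n_codons = len(cds) // 3
    gc = 0
    total = 0
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS and i == n_codons - 1:
            break
        third = codon[2]
        if third not in "ACGT":
            continue
        total += 1
        if third in "GC":
            gc += 1
    return gc / total if total else None


def expected_enc(s: float) -> float:
    """Expected ENC at GC3 = s under random codon usage:
    2 + s + 29 / (s^2 + (1-s)^2)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass
class EncResult:
    gene_id: str
    enc: Optional[float]
    gc3: Optional[float]
    expected_enc_at_gc3: Optional[float]
    below_curve: Optional[bool]
    category: Optional[str] = None


def enc_for_gene(gene: GeneRecord) -> EncResult:
    """ENC/GC3 result for one gene, with the below-curve classification."""
    e = enc(count_codons(gene.cds))
    g = gc3(gene.cds)
    exp = expected_enc(g) if g is not None else None
    below = (e < exp) if (e is not None and exp is not None) else None
    return EncResult(gene.gene_id, e, g, exp, below, gene.category)


def enc_comparison(
    unique_genes: Sequence[GeneRecord],
    all_genes: Sequence[GeneRecord],
) -> dict[str, dict]:
    """Compare per-category mean ENC of the focal-unique gene set vs the
    full gene set, plus below-curve fractions.

    Genes with undefined ENC are excluded from means and counted.
    """
    out: dict[str, dict] = {}
    for label, genes in (("unique", unique_genes), ("all", all_genes)):
        if not genes:
            raise ValueError(f"{label} gene set is empty")
        results = [enc_for_gene(g) for g in genes]
        defined = [r for r in results if r.enc is not None]
        by_cat: dict[str, list[float]] = {}
        for r in defined:
            if r.category:
                by_cat.setdefault(r.category, []).append(r.enc)
        below = [r for r in defined if r.below_curve]
        out[label] = {
            "mean_enc_by_category": {c: sum(v) / len(v) for c, v in sorted(by_cat.items())},
            "mean_enc": sum(r.enc for r in defined) / len(defined) if defined else None,
            "below_curve_fraction": len(below) / len(defined) if defined else None,
            "n_defined": len(defined),
            "n_undefined": len(results) - len(defined),
        }
    return out
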