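"""Synthetic clade generator with full ground truth.

Emulates the statistical structure the comparative analysis assumes: a
clade of focal ("hadal") and background ("surface relative") genomes
derived from a common ancestor by substitution-only evolution, with

* per-genome nucleotide divergence targets (so pairwise ANI is planted),
* per-category amino-acid divergence multipliers (so the rank-decile
  variation analysis has a planted signal),
* focal-only unique genes drawn from weighted functional categories (so
  unique-cluster detection and enrichment are testable),
* codon usage drawn from Zipf-like per-amino-acid weights scaled by a
  bias strength (so ENC gradients are planted), and
* depth-structured per-sample genome abundances from which reads are
  simulated (so RPKG recovery is testable).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    CODON_TO_AA,
    STOP_CODONS,
    GeneRecord,
    GenomeRecord,
    Role,
    reverse_complement,
    translate_cds,
)

__all__ = [
    "CladeConfig",
    "CladeTruth",
    "simulate_clade",
    "mutate_gene",
    "simulate_reads",
    "generate_gene",
    "random_protein",
]

_AA_ORDER = sorted({aa for aa in CODON_TO_AA.values()})
#: codons per amino acid in a fixed order (rank order for the Zipf weights)
_FAMILY: dict[str, list[str]] = {
    aa: sorted(c for c, a in CODON_TO_AA.items() if a == aa) for aa in _AA_ORDER
}

# 1-nt neighbours of each sense codon, split by effect
_SYN_NEIGHBORS: dict[str, list[str]] = {}
_NONSYN_NEIGHBORS: dict[str, list[str]] = {}
for _c in CODON_TO_AA:
    syn, nonsyn = [], []
    for _i in range(3):
        for _b in "ACGT":
            if _b == _c[_i]:
                continue
            alt = _c[:_i] + _b + _c[_i + 1 :]
            if alt in STOP_CODONS:
                continue
            (syn if CODON_TO_AA[alt] == CODON_TO_AA[_c] else nonsyn).append(alt)
    _SYN_NEIGHBORS[_c] = syn
    _NONSYN_NEIGHBORS[_c] = nonsyn

#: default category pool for core genes (roughly COG-like usage)
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "C": 6, "E": 9, "F": 2, "G": 7, "H": 4, "I": 4, "J": 6, "K": 6,
    "L": 5, "M": 6, "N": 2, "O": 4, "P": 6, "R": 10, "S": 8, "T": 5,
    "U": 2, "V": 2, "W": 1, "X": 4,
}


@dataclass
class CladeConfig:
    """Study conditions for one simulated clade.

    ``ani_targets`` are per-genome nucleotide divergence *fractions* versus
    the common ancestor (focal genomes first, then background); planted
    pairwise divergence between two derived genomes is approximately the
    sum of their values.
    """

    n_focal: int = 2
    n_background: int = 2
    n_core_genes: int = 100
    gene_length_codons: tuple[int, int] = (150, 350)
    ani_targets: Optional[Sequence[float]] = None
    unique_genes_per_focal: int = 10
    unique_category_weights: dict[str, float] = field(
        default_factory=lambda: {"X": 3, "M": 2, "K": 2, "P": 1, "R": 1, "S": 1}
    )
    divergence_class_by_category: dict[str, float] = field(default_factory=dict)
    codon_bias_strength: float = 0.6
    unique_codon_bias_strength: float = 0.2
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    nonsyn_fraction: float = 0.35
    intergenic_len: int = 60
    n_contigs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ani_targets is None:
            self.ani_targets = [0.02] * (self.n_focal + self.n_background)
        if len(self.ani_targets) != self.n_focal + self.n_background:
            raise ValueError("ani_targets must have one entry per genome")
        for d in self.ani_targets:
            if not 0.0 <= d <= 0.35:
                raise ValueError(f"divergence {d} outside [0, 0.35]")
        if not self.unique_category_weights or all(
            w <= 0 for w in self.unique_category_weights.values()
        ):
            raise ValueError("unique_category_weights needs a positive weight")
        if any(w < 0 for w in self.unique_category_weights.values()):
            raise ValueError("unique_category_weights must be nonnegative")


@dataclass
class CladeTruth:
    """Ground truth planted by the generator."""

    family_of_gene: dict[str, str] = field(default_factory=dict)
    unique_gene_ids: set[str] = field(default_factory=set)
    planted_divergence: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_nt_divergence: dict[str, float] = field(default_factory=dict)
    abundance: Optional[np.ndarray] = None
    sample_ids: list[str] = field(default_factory=list)
    genome_ids: list[str] = field(default_factory=list)
    read_origin: dict[str, tuple[str, int]] = field(default_factory=dict)


def _codon_weights(strength: float) -> dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon weights: Zipf-like, rank r gets
    weight (r+1)^(-4*strength); strength 0 means uniform usage."""
    out = {}
    for aa, codons in _FAMILY.items():
        w = np.array([(r + 1) ** (-4.0 * strength) for r in range(len(codons))])
        out[aa] = w / w.sum()
    return out


def random_protein(rng: np.random.Generator, n_codons: int) -> str:
    """Random amino-acid sequence starting with Met."""
    aas = [a for a in _AA_ORDER]
    idx = rng.integers(0, len(aas), size=n_codons - 1)
    return "M" + "".join(aas[i] for i in idx)


def generate_gene(
    rng: np.random.Generator,
    n_codons: int,
    codon_bias_strength: float,
    weights: Optional[dict[str, np.ndarray]] = None,
) -> str:
    """Generate a CDS (with trailing stop) for a random protein, drawing
    synonymous codons from the biased weight vectors."""
    if weights is None:
        weights = _codon_weights(codon_bias_strength)
    cum = {aa: w.cumsum() for aa, w in weights.items()}
    protein = random_protein(rng, n_codons)
    u = rng.random(n_codons)
    codons = []
    for i, aa in enumerate(protein):
        fam = _FAMILY[aa]
        if len(fam) == 1:
            codons.append(fam[0])
        else:
            codons.append(fam[min(int(np.searchsorted(cum[aa], u[i])), len(fam) - 1)])
    codons.append("TAA")
    return "".join(codons)


def _substitute_nonsyn(codons: list[str], n_changes: int, rng: np.random.Generator) -> int:
    """Mutate ``n_changes`` distinct codons to a 1-nt-different codon that
    changes the amino acid (never a stop).  Returns changes made."""
    eligible = [i for i, c in enumerate(codons) if _NONSYN_NEIGHBORS[c]]
    n = min(n_changes, len(eligible))
    if n == 0:
        return 0
    picks = rng.choice(len(eligible), size=n, replace=False)
    for p in picks:
        i = eligible[p]
        alts = _NONSYN_NEIGHBORS[codons[i]]
        codons[i] = alts[rng.integers(0, len(alts))]
    return n


def _substitute_syn(
    codons: list[str], n_changes: int, rng: np.random.Generator, exclude: set[int]
) -> int:
    eligible = [
        i for i, c in enumerate(codons) if i not in exclude and _SYN_NEIGHBORS[c]
    ]
    n = min(n_changes, len(eligible))
    if n == 0:
        return 0
    picks = rng.choice(len(eligible), size=n, replace=False)
    for p in picks:
        i = eligible[p]
        alts = _SYN_NEIGHBORS[codons[i]]
        codons[i] = alts[rng.integers(0, len(alts))]
    return n


def mutate_gene(
    cds: str,
    target_aa_divergence: float,
    rng: np.random.Generator,
    synonymous_rate: float = 0.0,
) -> str:
    """Mutate a CDS to a target amino-acid divergence.

    Nonsynonymous substitutions are introduced at distinct codons until
    the realised protein divergence is within one amino acid of the target
    count; synonymous substitutions are added independently at
    ``synonymous_rate`` per codon.  No internal stop is ever created.
    """
    if not 0.0 <= target_aa_divergence <= 0.5:
        raise ValueError("target amino-acid divergence must be in [0, 0.5]")
    body = cds[:-3] if cds[-3:] in STOP_CODONS else cds
    tail = cds[len(body):]
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    n_codons = len(codons)
    target_count = round(target_aa_divergence * n_codons)
    changed: set[int] = set()
    before = list(codons)
    made = _substitute_nonsyn(codons, target_count, rng)
    changed = {i for i in range(n_codons) if codons[i] != before[i]}
    if abs(made - target_count) > 1:
        raise RuntimeError("could not reach the target amino-acid divergence")
    if synonymous_rate > 0:
        n_syn = rng.binomial(n_codons, synonymous_rate)
        _substitute_syn(codons, n_syn, rng, exclude=changed)
    return "".join(codons) + tail


def _mutate_gene_budgeted(
    cds: str,
    nt_budget: int,
    aa_multiplier: float,
    nonsyn_fraction: float,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Mutate a CDS spending a fixed nucleotide-substitution budget.

    Amino-acid changes (one nucleotide each) take
    round(nonsyn_fraction * aa_multiplier * budget); the remainder is spent
    on synonymous substitutions at distinct codons.  Returns the mutated
    CDS and the realised amino-acid divergence fraction.
    """
    body = cds[:-3] if cds[-3:] in STOP_CODONS else cds
    tail = cds[len(body):]
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    n_codons = len(codons)
    aa_target = min(round(nonsyn_fraction * aa_multiplier * nt_budget), nt_budget, n_codons)
    before = list(codons)
    made_aa = _substitute_nonsyn(codons, aa_target, rng)
    changed = {i for i in range(n_codons) if codons[i] != before[i]}
    _substitute_syn(codons, nt_budget - made_aa, rng, exclude=changed)
    return "".join(codons) + tail, made_aa / n_codons


def simulate_clade(
    config: CladeConfig,
) -> tuple[list[GenomeRecord], list[GeneRecord], CladeTruth]:
    """Generate the clade: ancestor, derived genomes, genes, ground truth."""
    rng = np.random.default_rng(config.seed)
    truth = CladeTruth()

    lo, hi = config.gene_length_codons
    core_weights = _codon_weights(config.codon_bias_strength)
    unique_weights = _codon_weights(config.unique_codon_bias_strength)

    cat_pool = sorted(config.category_weights)
    cat_p = np.array([config.category_weights[c] for c in cat_pool], dtype=float)
    cat_p /= cat_p.sum()

    # --- ancestor core genes
    ancestor: list[tuple[str, str, str]] = []  # (family_id, category, cds)
    for j in range(config.n_core_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        cds = generate_gene(rng, n_codons, config.codon_bias_strength, core_weights)
        category = cat_pool[rng.choice(len(cat_pool), p=cat_p)]
        ancestor.append((f"fam{j:05d}", category, cds))

    ucat_pool = sorted(c for c, w in config.unique_category_weights.items() if w > 0)
    ucat_p = np.array([config.unique_category_weights[c] for c in ucat_pool], dtype=float)
    ucat_p /= ucat_p.sum()

    genome_ids = [f"F{i + 1:02d}" for i in range(config.n_focal)] + [
        f"B{i + 1:02d}" for i in range(config.n_background)
    ]
    roles = [Role.FOCAL] * config.n_focal + [Role.BACKGROUND] * config.n_background

    genomes: list[GenomeRecord] = []
    genes: list[GeneRecord] = []
    bases = np.array(list("ACGT"))

    def spacer(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=n)])

    def mutate_spacer(seq: str, d: float) -> str:
        n = round(d * len(seq))
        if n == 0:
            return seq
        chars = list(seq)
        pos = rng.choice(len(chars), size=min(n, len(chars)), replace=False)
        for p in pos:
            alts = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alts[rng.integers(0, 3)]
        return "".join(chars)

    # fixed ancestral intergenic spacers, mutated per genome
    spacers = [spacer(config.intergenic_len) for _ in range(config.n_core_genes + 1)]

    for gid, role, d in zip(genome_ids, roles, config.ani_targets):
        parts: list[str] = []
        coords: list[tuple[str, str, int, int, str]] = []  # gene_id, cat, start, end, cds
        pos = 0

        def append_seq(s: str) -> None:
            nonlocal pos
            parts.append(s)
            pos += len(s)

        for k, (fam, category, anc_cds) in enumerate(ancestor):
            append_seq(mutate_spacer(spacers[k], d))
            nt_budget = round(d * len(anc_cds))
            mult = config.divergence_class_by_category.get(category, 1.0)
            cds, aa_div = _mutate_gene_budgeted(
                anc_cds, nt_budget, mult, config.nonsyn_fraction, rng
            )
            gene_id = f"{gid}_{fam}"
            coords.append((gene_id, category, pos + 1, pos + len(cds), cds))
            append_seq(cds)
            truth.family_of_gene[gene_id] = fam
            truth.planted_divergence[(gid, gene_id)] = aa_div
        append_seq(mutate_spacer(spacers[-1], d))

        if role is Role.FOCAL:
            for u in range(config.unique_genes_per_focal):
                n_codons = int(rng.integers(lo, hi + 1))
                cds = generate_gene(
                    rng, n_codons, config.unique_codon_bias_strength, unique_weights
                )
                category = ucat_pool[rng.choice(len(ucat_pool), p=ucat_p)]
                gene_id = f"{gid}_uniq{u:04d}"
                append_seq(spacer(config.intergenic_len))
                coords.append((gene_id, category, pos + 1, pos + len(cds), cds))
                append_seq(cds)
                truth.unique_gene_ids.add(gene_id)
                truth.family_of_gene[gene_id] = f"ufam_{gene_id}"

        contig_seq = "".join(parts)
        contig_id = f"{gid}_c1"
        genome = GenomeRecord(gid, [(contig_id, contig_seq)], role=role)
        genomes.append(genome)
        truth.planted_nt_divergence[gid] = d
        for gene_id, category, start, end, cds in coords:
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=gid,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+",
                    cds=cds,
                    protein=translate_cds(cds),
                    category=category,
                )
            )

    truth.genome_ids = genome_ids
    return genomes, genes, truth


def simulate_divergent_proteome(
    rng: np.random.Generator,
    categories: Sequence[str] = tuple("CEGJKLMPRX"),
    genes_per_category: int = 60,
    gene_length_codons: int = 120,
    multiplier_by_category: Optional[dict[str, float]] = None,
    base_divergence_min: float = 0.02,
    base_divergence_mean: float = 0.06,
    max_divergence: float = 0.45,
    codon_bias_strength: float = 0.3,
) -> tuple[list[tuple[str, str, str]], dict[str, str], dict[str, float]]:
    """Generate a (focal, background) ortholog pair set for the rank-decile
    variation analysis, with per-category divergence multipliers.

    The per-gene base amino-acid divergence is heavy-tailed
    (``base_divergence_min`` plus an exponential with the given mean),
    mirroring the skew of real ortholog divergence: most genes conserved,
    a minority fast-evolving.  Each gene's divergence is the base times its
    category's multiplier, capped at ``max_divergence``.

    Returns (queries, background_proteome, planted_divergence) where
    queries is a list of (gene_id, category, protein).
    """
    multiplier_by_category = multiplier_by_category or {}
    queries: list[tuple[str, str, str]] = []
    background: dict[str, str] = {}
    planted: dict[str, float] = {}
    for cat in categories:
        mult = multiplier_by_category.get(cat, 1.0)
        for j in range(genes_per_category):
            gene_id = f"{cat}{j:04d}"
            cds = generate_gene(rng, gene_length_codons, codon_bias_strength)
            background[f"bg_{gene_id}"] = translate_cds(cds)
            d = min(
                (base_divergence_min + rng.exponential(base_divergence_mean)) * mult,
                max_divergence,
            )
            mutated = mutate_gene(cds, d, rng)
            queries.append((gene_id, cat, translate_cds(mutated)))
            planted[gene_id] = d
    return queries, background, planted


def depth_structured_abundances(
    genome_ids: Sequence[str],
    depths_m: Sequence[float],
    rng: np.random.Generator,
    bandwidth_m: float = 2500.0,
    floor: float = 0.02,
) -> np.ndarray:
    """Genome x sample relative abundances with a depth preference per
    genome: a Gaussian kernel around a preferred depth plus a small floor;
    columns sum to 1."""
    depths = np.asarray(depths_m, dtype=float)
    mat = np.zeros((len(genome_ids), len(depths)))
    for i in range(len(genome_ids)):
        preferred = depths[rng.integers(0, len(depths))]
        mat[i] = np.exp(-((depths - preferred) ** 2) / (2 * bandwidth_m**2)) + floor
        mat[i] *= float(rng.uniform(0.5, 1.5))
    return mat / mat.sum(axis=0, keepdims=True)


def simulate_reads(
    genomes: Sequence[GenomeRecord],
    abundances: Sequence[float],
    n_reads: int,
    read_length_bp: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, int]]]:
    """Simulate reads from a community.

    Reads are drawn genome-proportional to abundance x genome length (so
    that RPKG, which divides by genome length, recovers the configured
    relative abundances), with uniform start positions, a random strand,
    and independent per-base substitution errors.  Returns the reads and a
    read_id -> (genome_id, forward-strand start position) origin map.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    ab = np.asarray(abundances, dtype=float)
    if abs(ab.sum() - 1.0) > 1e-8:
        raise ValueError("abundances must sum to 1")
    lengths = np.array([g.genome_length_bp for g in genomes], dtype=float)
    for g in genomes:
        if min(len(s) for _, s in g.contigs) < read_length_bp:
            raise ValueError("read length exceeds the shortest contig")
    rng = np.random.default_rng(seed)
    weights = ab * lengths
    weights /= weights.sum()
    picks = rng.choice(len(genomes), size=n_reads, p=weights)
    bases = "ACGT"
    reads: list[tuple[str, str]] = []
    origin: dict[str, tuple[str, int]] = {}
    for r, gi in enumerate(picks):
        genome = genomes[gi]
        clens = np.array([len(s) for _, s in genome.contigs], dtype=float)
        ci = int(rng.choice(len(clens), p=clens / clens.sum()))
        contig_id, seq = genome.contigs[ci]
        start = int(rng.integers(0, len(seq) - read_length_bp + 1))
        fragment = seq[start : start + read_length_bp]
        if rng.random() < 0.5:
            fragment = reverse_complement(fragment)
        if error_rate > 0:
            chars = list(fragment)
            errs = np.flatnonzero(rng.random(read_length_bp) < error_rate)
            for p in errs:
                alts = [b for b in bases if b != chars[p]]
                chars[p] = alts[rng.integers(0, 3)]
            fragment = "".join(chars)
        read_id = f"read{r:07d}"
        reads.append((read_id, fragment))
        origin[read_id] = (genome.genome_id, start)
    return reads, origin
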