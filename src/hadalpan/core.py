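"""Domain types shared by every stage of the pipeline.

The pipeline compares a set of *focal* genomes (hadal single-amplified
genomes) against *background* relatives (surface-water reference genomes).
Genes carry an optional one-letter COG functional category; the vocabulary
is the standard 26-letter scheme (A-Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio.Data import CodonTable

__all__ = [
    "COG_CATEGORIES",
    "GenomeRecord",
    "GeneRecord",
    "SampleMeta",
    "Role",
    "SizeFraction",
    "translate_cds",
    "reverse_complement",
    "CODON_TO_AA",
    "STOP_CODONS",
]

#: One-letter COG functional categories (A-Z as in the standard scheme;
#: X = mobilome, M = cell wall/membrane/envelope biogenesis, ...).
COG_CATEGORIES: frozenset[str] = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class Role(str, Enum):
    """Whether a genome is a hadal focal genome or a background relative."""

    FOCAL = "focal"
    BACKGROUND = "background"


class SizeFraction(str, Enum):
    FREE_LIVING = "free_living"
    PARTICLE_ASSOCIATED = "particle_associated"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One genome: ordered contigs plus its role in the comparison.

    ``genome_length_bp`` is the sum of contig lengths and is what the
    RPKG normalisation divides by (genome size Gx).
    """

    genome_id: str
    contigs: list[tuple[str, str]]
    role: Role = Role.FOCAL
    genome_length_bp: int = field(init=False)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in genome {self.genome_id}")
        for cid, seq in self.contigs:
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(
                    f"contig {cid} of {self.genome_id} contains characters "
                    "outside A/C/G/T/N (or is empty)"
                )
        self.genome_length_bp = sum(len(s) for _, s in self.contigs)
        if self.genome_length_bp <= 0:
            raise ValueError(f"genome {self.genome_id} is empty")

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(f"contig {contig_id} not in genome {self.genome_id}")


@dataclass
class GeneRecord:
    """One protein-coding gene located on a contig.

    Coordinates are 1-based inclusive on the forward strand; strand '-'
    means the CDS is the reverse complement of the slice.  ``protein`` is
    the translation with the trailing stop removed.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds: str
    protein: str
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.category is not None and self.category not in COG_CATEGORIES:
            raise ValueError(
                f"gene {self.gene_id}: unknown functional category "
                f"{self.category!r}"
            )


@dataclass
class SampleMeta:
    """A metagenomic sample: depth, size fraction, and library size in bp.

    ``metagenome_size_bp`` is the metagenome size MG used by the RPKG
    normalisation.
    """

    sample_id: str
    depth_m: float
    size_fraction: SizeFraction
    metagenome_size_bp: int

    def __post_init__(self) -> None:
        if self.metagenome_size_bp <= 0:
            raise ValueError(f"sample {self.sample_id}: metagenome size must be > 0")


class TranslationError(ValueError):
    pass


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard bacterial usage rules.

    A trailing stop codon is stripped; an internal stop is an error (its
    codon position is reported); any codon containing a base outside
    A/C/G/T translates to 'X'.

    Parameters
    ----------
    cds : str
        Nucleotide sequence whose length is divisible by 3.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} is not a multiple of 3")
    n_codons = len(cds) // 3
    aas: list[str] = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break  # trailing stop: strip
            raise TranslationError(
                f"internal stop codon {codon} at codon position {i + 1}"
            )
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)
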