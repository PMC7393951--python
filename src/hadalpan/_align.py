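"""Shared protein-alignment machinery: a BLOSUM62 global aligner with
affine gaps (open 11, extend 1) and a k-mer prefilter for candidate
selection, used by both the ortholog-clustering and the top-hit-identity
stages."""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "make_aligner",
    "global_identity",
    "alignment_score",
    "kmer_candidates",
    "ProteinSet",
]

DEFAULT_KMER = 4


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = make_aligner()


def alignment_score(a: str, b: str) -> float:
    if not a or not b:
        raise ValueError("empty protein sequence")
    return _ALIGNER.score(a, b)


def global_identity(a: str, b: str) -> tuple[float, float]:
    """Global BLOSUM62/affine(11,1) alignment of two proteins.

    Returns (identity percent over aligned columns including gap columns,
    alignment score).
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    identity = 100.0 * counts.identities / alignment.length
    return identity, alignment.score


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class ProteinSet:
    """A k-mer-indexed collection of proteins supporting candidate lookup.

    ``candidates(query)`` returns ids sharing at least one exact k-mer with
    the query, ranked by the number of shared k-mers (descending, then id)
    and optionally capped — a seeding heuristic that keeps the number of
    full alignments bounded.
    """

    def __init__(self, proteins: dict[str, str], k: int = DEFAULT_KMER):
        self.k = k
        self.proteins = proteins
        self.index: dict[str, list[str]] = {}
        for pid, seq in proteins.items():
            for kmer in _kmers(seq, k):
                self.index.setdefault(kmer, []).append(pid)

    def candidates(self, query: str, max_candidates: Optional[int] = None) -> list[str]:
        shared: Counter = Counter()
        for kmer in _kmers(query, self.k):
            for pid in self.index.get(kmer, ()):
                shared[pid] += 1
        ranked = sorted(shared, key=lambda pid: (-shared[pid], pid))
        if max_candidates is not None:
            ranked = ranked[:max_candidates]
        return ranked


def kmer_candidates(query: str, targets: dict[str, str], k: int = DEFAULT_KMER) -> list[str]:
    """Ids of targets sharing at least one exact k-mer with the query."""
    qk = _kmers(query, k)
    return [pid for pid, seq in targets.items() if qk & _kmers(seq, k)]
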