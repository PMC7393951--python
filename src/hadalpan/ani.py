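"""Fragment-based average nucleotide identity (ANI).

The query genome is cut into consecutive non-overlapping windows (1 kb by
default); each fragment is placed on the target genome by exact shared
k-mers on both strands and scored by ungapped extension over the full
fragment.  ANI is the mean identity over fragments with an accepted hit,
averaged over both directions.  Background genomes with ANI strictly above
95% to at least one focal genome are "closely related" relatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import GenomeRecord, reverse_complement

__all__ = [
    "AniResult",
    "fragment_genome",
    "best_fragment_identity",
    "ani",
    "ani_matrix",
    "select_close_relatives",
]

DEFAULT_FRAGMENT_LEN = 1000
DEFAULT_K = 15
MIN_ALIGNED_FRACTION = 0.7
MIN_FRAGMENT_IDENTITY = 30.0


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani_percent: Optional[float]
    n_fragments_used: int
    coverage_fraction: float


def fragment_genome(genome: GenomeRecord, fragment_len: int = DEFAULT_FRAGMENT_LEN) -> list[str]:
    """Consecutive non-overlapping windows per contig; a terminal remainder
    shorter than ``fragment_len`` is discarded."""
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    frags: list[str] = []
    for _, seq in genome.contigs:
        for i in range(0, len(seq) - fragment_len + 1, fragment_len):
            frags.append(seq[i : i + fragment_len])
    return frags


class _KmerIndex:
    """Exact k-mer positions over both strands of a genome's contigs."""

    def __init__(self, genome: GenomeRecord, k: int):
        self.k = k
        self.seqs: list[str] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for _, seq in genome.contigs:
            for s in (seq, reverse_complement(seq)):
                sid = len(self.seqs)
                self.seqs.append(s)
                for i in range(len(s) - k + 1):
                    kmer = s[i : i + k]
                    if "N" in kmer:
                        continue
                    self.index.setdefault(kmer, []).append((sid, i))


def _ungapped_identity(fragment: str, target: str, offset: int) -> tuple[float, float]:
    """Identity of the fragment laid on ``target`` at diagonal ``offset``
    (target position of fragment position 0), clipped to target bounds.

    Returns (identity percent over aligned positions, aligned fraction of
    the fragment).
    """
    lo = max(0, -offset)
    hi = min(len(fragment), len(target) - offset)
    if hi <= lo:
        return 0.0, 0.0
    matches = sum(
        1 for i in range(lo, hi) if fragment[i] == target[offset + i]
    )
    aligned = hi - lo
    return 100.0 * matches / aligned, aligned / len(fragment)


def best_fragment_identity(
    fragment: str,
    target: GenomeRecord,
    k: int = DEFAULT_K,
    index: Optional[_KmerIndex] = None,
) -> Optional[tuple[float, float]]:
    """Best ungapped placement of a fragment on a target genome.

    Returns (identity percent, aligned fraction), or None when no shared
    k-mer exists or the best placement fails the aligned-fraction (0.7) or
    identity (30%) acceptance thresholds.
    """
    if index is None:
        index = _KmerIndex(target, k)
    candidates: set[tuple[int, int]] = set()
    for i in range(0, len(fragment) - index.k + 1):
        kmer = fragment[i : i + index.k]
        for sid, pos in index.index.get(kmer, ()):
            candidates.add((sid, pos - i))
    best: Optional[tuple[float, float]] = None
    for sid, offset in sorted(candidates):
        ident, frac = _ungapped_identity(fragment, index.seqs[sid], offset)
        if best is None or ident > best[0]:
            best = (ident, frac)
    if best is None or best[1] < MIN_ALIGNED_FRACTION or best[0] < MIN_FRAGMENT_IDENTITY:
        return None
    return best


def _one_way_ani(query: GenomeRecord, target: GenomeRecord, fragment_len: int, k: int) -> tuple[Optional[float], int, float]:
    frags = fragment_genome(query, fragment_len)
    if not frags:
        return None, 0, 0.0
    index = _KmerIndex(target, k)
    idents = []
    for frag in frags:
        hit = best_fragment_identity(frag, target, k, index=index)
        if hit is not None:
            idents.append(hit[0])
    if not idents:
        return None, 0, 0.0
    return sum(idents) / len(idents), len(idents), len(idents) / len(frags)


def ani(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    k: int = DEFAULT_K,
) -> AniResult:
    """Symmetric fragment ANI: the mean of both directional estimates.

    When no fragment in either direction finds an accepted hit the result
    carries ``ani_percent=None`` (an explicit no-estimate, not a number).
    """
    ab, n_ab, cov_ab = _one_way_ani(genome_a, genome_b, fragment_len, k)
    ba, n_ba, cov_ba = _one_way_ani(genome_b, genome_a, fragment_len, k)
    values = [v for v in (ab, ba) if v is not None]
    return AniResult(
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        ani_percent=sum(values) / len(values) if values else None,
        n_fragments_used=n_ab + n_ba,
        coverage_fraction=(cov_ab + cov_ba) / 2.0,
    )


def ani_matrix(genomes: Sequence[GenomeRecord], fragment_len: int = DEFAULT_FRAGMENT_LEN, k: int = DEFAULT_K) -> dict[tuple[str, str], AniResult]:
    """All unordered pairs; result stored under both key orders."""
    out: dict[tuple[str, str], AniResult] = {}
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            res = ani(a, b, fragment_len, k)
            out[(a.genome_id, b.genome_id)] = res
            out[(b.genome_id, a.genome_id)] = res
    return out


def select_close_relatives(
    ani_results: dict[tuple[str, str], AniResult],
    focal_ids: Sequence[str],
    background_ids: Sequence[str],
    threshold: float = 95.0,
) -> set[str]:
    """Background genomes with ANI strictly above ``threshold`` percent to
    at least one focal genome."""
    selected: set[str] = set()
    for b in background_ids:
        for f in focal_ids:
            res = ani_results.get((f, b)) or ani_results.get((b, f))
            if res is None:
                raise KeyError(f"missing ANI result for pair ({f}, {b})")
            if res.ani_percent is not None and res.ani_percent > threshold:
                selected.add(b)
                break
    return selected
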