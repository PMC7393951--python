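"""Rank-decile amino-acid-variation analysis.

Each annotated focal gene is compared against the background proteomes;
the identity of its best-scoring hit gives a per-gene dissimilarity
(100 - identity).  Genes are ranked by dissimilarity and divided equally
into ten intervals; within each interval the relative abundance of every
functional category is computed, and each category's abundance profile is
tested for Pearson correlation against the intervals' mean dissimilarity.
Categories with a significant positive correlation (p < 0.01) are those
whose proteins diverge fastest from the background relatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import t as t_dist

from ._align import ProteinSet, alignment_score, global_identity

__all__ = [
    "VariationRecord",
    "CategoryCorrelation",
    "top_hit_identity",
    "rank_into_bins",
    "category_bin_profile",
    "category_correlation",
    "calibrate_score_threshold",
]

DEFAULT_MIN_SCORE = 50.0
P_CUTOFF = 0.01


@dataclass
class VariationRecord:
    gene_id: str
    category: Optional[str]
    top_hit_identity: Optional[float]
    bin_index: Optional[int] = None

    @property
    def dissimilarity(self) -> Optional[float]:
        if self.top_hit_identity is None:
            return None
        return 100.0 - self.top_hit_identity


@dataclass
class CategoryCorrelation:
    category: str
    pearson_r: Optional[float]
    p_value: Optional[float]
    significant: bool
    reason: Optional[str] = None


def top_hit_identity(
    query: str,
    background: ProteinSet,
    min_score: float = DEFAULT_MIN_SCORE,
    max_candidates: Optional[int] = 50,
) -> Optional[float]:
    """Identity (percent) of the best-scoring global alignment of the
    query against the background proteomes, or None when no candidate
    shares a 4-mer or no alignment reaches ``min_score``.

    The raw score threshold stands in for a database E-value cutoff; see
    :func:`calibrate_score_threshold`.
    """
    best_score: Optional[float] = None
    best_id: Optional[str] = None
    for cand in background.candidates(query, max_candidates):
        s = alignment_score(query, background.proteins[cand])
        if best_score is None or s > best_score or (s == best_score and cand < best_id):
            best_score, best_id = s, cand
    if best_score is None or best_score < min_score:
        return None
    identity, _ = global_identity(query, background.proteins[best_id])
    return identity


def calibrate_score_threshold(
    proteins: Sequence[str],
    rng: np.random.Generator,
    false_positive_rate: float = 0.01,
    n_pairs: int = 500,
) -> float:
    """Score threshold such that shuffled (unrelated) protein pairs exceed
    it at most ``false_positive_rate`` of the time.

    Pairs of proteins are drawn, each shuffled independently to destroy
    homology while preserving composition, and the (1 - fpr) quantile of
    their alignment scores is returned.
    """
    scores = []
    pool = [p for p in proteins if p]
    if len(pool) < 2:
        raise ValueError("need at least two proteins to calibrate")
    for _ in range(n_pairs):
        a, b = rng.choice(len(pool), size=2, replace=False)
        sa = "".join(rng.permutation(list(pool[a])))
        sb = "".join(rng.permutation(list(pool[b])))
        scores.append(alignment_score(sa, sb))
    return float(np.quantile(scores, 1.0 - false_positive_rate))


def rank_into_bins(records: Sequence[VariationRecord], n_bins: int = 10) -> list[VariationRecord]:
    """Sort records by dissimilarity ascending (ties by gene_id) and assign
    bin indices 1..n_bins with sizes differing by at most one, larger bins
    first.  Records without an accepted hit are excluded."""
    usable = [r for r in records if r.top_hit_identity is not None]
    if len(usable) < n_bins:
        raise ValueError(
            f"need at least {n_bins} records with a hit, got {len(usable)}"
        )
    usable.sort(key=lambda r: (r.dissimilarity, r.gene_id))
    q, rem = divmod(len(usable), n_bins)
    idx = 0
    for b in range(1, n_bins + 1):
        size = q + 1 if b <= rem else q
        for r in usable[idx : idx + size]:
            r.bin_index = b
        idx += size
    return usable


def category_bin_profile(
    binned: Sequence[VariationRecord], n_bins: int = 10
) -> tuple[dict[str, list[float]], list[float]]:
    """Within-bin relative abundance of each category plus each bin's mean
    dissimilarity.  Every category present anywhere gets a full row with
    explicit zeros; each bin's proportions sum to 1."""
    categories = sorted({r.category for r in binned if r.category})
    profile = {c: [0.0] * n_bins for c in categories}
    mean_diss: list[float] = []
    for b in range(1, n_bins + 1):
        in_bin = [r for r in binned if r.bin_index == b]
        if not in_bin:
            raise ValueError(f"bin {b} is empty")
        annotated = [r for r in in_bin if r.category]
        for c in categories:
            n_c = sum(1 for r in annotated if r.category == c)
            profile[c][b - 1] = n_c / len(annotated) if annotated else 0.0
        mean_diss.append(sum(r.dissimilarity for r in in_bin) / len(in_bin))
    return profile, mean_diss


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r from the covariance formula, with a two-sided p from the
    t statistic r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    n = len(x)
    xm = x - x.mean()
    ym = y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm * xm).sum() * (ym * ym).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def category_correlation(
    profile: dict[str, list[float]],
    mean_dissimilarities: Sequence[float],
    p_cutoff: float = P_CUTOFF,
) -> list[CategoryCorrelation]:
    """Per-category Pearson correlation of within-bin relative abundance
    against the bins' mean dissimilarity."""
    diss = np.asarray(mean_dissimilarities, dtype=float)
    if len(diss) < 3:
        raise ValueError("need at least 3 bins")
    out: list[CategoryCorrelation] = []
    for category in sorted(profile):
        y = np.asarray(profile[category], dtype=float)
        if len(y) != len(diss):
            raise ValueError(f"profile row for {category} has wrong length")
        if np.ptp(y) == 0.0 or np.ptp(diss) == 0.0:
            out.append(
                CategoryCorrelation(category, None, None, False, reason="zero variance")
            )
            continue
        r, p = _pearson(diss, y)
        out.append(CategoryCorrelation(category, r, p, p < p_cutoff))
    return out
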