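"""Independent oracle implementations used to cross-check the package.

Everything here is coded from first principles (its own codon table, its
own dynamic-programming alignment, its own agglomerative clustering) so
that agreement with the package is informative.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# standard genetic code, spelled out independently of the package
_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE: dict[str, str] = {}
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA_TABLE[16 * _i + 4 * _j + _k]


def wright_enc_oracle(cds: str) -> float | None:
    """Step-by-step Wright effective-number-of-codons computation."""
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and CODON_TABLE.get(codons[-1]) == "*":
        codons = codons[:-1]
    usage: dict[str, dict[str, int]] = {}
    for codon in codons:
        aa = CODON_TABLE.get(codon)
        if aa is None or aa == "*":
            continue
        usage.setdefault(aa, {})
        usage[aa][codon] = usage[aa].get(codon, 0) + 1

    # family sizes under the standard code
    fam_size: dict[str, int] = {}
    for codon, aa in CODON_TABLE.items():
        if aa != "*":
            fam_size[aa] = fam_size.get(aa, 0) + 1

    def f_hat(counts: dict[str, int]) -> float | None:
        n = sum(counts.values())
        if n < 2:
            return None
        s = sum((c / n) ** 2 for c in counts.values())
        f = (n * s - 1.0) / (n - 1.0)
        return f if f > 0 else None

    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, counts in usage.items():
        size = fam_size[aa]
        if size == 1:
            continue
        f = f_hat(counts)
        if f is not None:
            class_f[size].append(f)

    means: dict[int, float | None] = {
        k: (sum(v) / len(v) if v else None) for k, v in class_f.items()
    }
    if means[3] is None:
        if means[2] is None or means[4] is None:
            return None
        means[3] = (means[2] + means[4]) / 2.0
    if means[2] is None or means[4] is None or means[6] is None:
        return None
    enc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(enc, 61.0)


# ---------------------------------------------------------------------------
# Gotoh global alignment with affine gaps (open 11, extend 1), BLOSUM62
def gotoh_global(a: str, b: str, matrix, open_cost: float = 11.0, extend_cost: float = 1.0):
    """Affine-gap global alignment; first gap residue costs ``open_cost``,
    each further residue ``extend_cost``.  Returns (score, aligned_a,
    aligned_b) for one optimal alignment."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Iy[0][j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - extend_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - extend_cost)
    score = max(M[n][m], Ix[n][m], Iy[n][m])

    # traceback (preference M, Ix, Iy on ties)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max(
        (("M", M[n][m]), ("Ix", Ix[n][m]), ("Iy", Iy[n][m])), key=lambda t: t[1]
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[a[i - 1], b[j - 1]]
            prev = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            for cand, val in (("M", M[i - 1][j - 1]), ("Ix", Ix[i - 1][j - 1]), ("Iy", Iy[i - 1][j - 1])):
                if math.isclose(val, prev):
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 or j > 0:
                if math.isclose(Ix[i][j], M[i - 1][j] - open_cost):
                    state = "M"
                else:
                    state = "Ix"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if j > 1 or i > 0:
                if math.isclose(Iy[i][j], M[i][j - 1] - open_cost):
                    state = "M"
                else:
                    state = "Iy"
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Iy"
        elif j == 0:
            state = "Ix"
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def identity_of_alignment(aligned_a: str, aligned_b: str) -> float:
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return 100.0 * matches / len(aligned_a)


# ---------------------------------------------------------------------------
# Pearson correlation closed form
def pearson_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx = x - x.mean()
    sy = y - y.mean()
    r = float(np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2)))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as t_dist

    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, p


# ---------------------------------------------------------------------------
# brute-force agglomerative clustering (complete linkage, Euclidean)
def complete_linkage_heights(points: np.ndarray) -> list[float]:
    """Merge heights of naive complete-linkage agglomeration."""
    clusters: list[list[int]] = [[i] for i in range(len(points))]

    def dist(c1: list[int], c2: list[int]) -> float:
        return max(
            float(np.linalg.norm(points[i] - points[j])) for i in c1 for j in c2
        )

    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


# ---------------------------------------------------------------------------
# brute-force competitive read assignment
def competitive_assign_oracle(hits) -> dict[str, str]:
    """Per-read linear scan: highest identity, then higher score, then
    lexicographically smallest genome id."""
    by_read: dict[str, list] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    def better(h, cur) -> bool:
        if h.percent_identity != cur.percent_identity:
            return h.percent_identity > cur.percent_identity
        if h.score != cur.score:
            return h.score > cur.score
        return h.genome_id < cur.genome_id

    out = {}
    for rid, hs in by_read.items():
        best = hs[0]
        for h in hs[1:]:
            if better(h, best):
                best = h
        out[rid] = best.genome_id
    return out
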