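"""Competitive metagenomic read recruitment and RPKG depth profiles.

Reads are aligned against all genomes at once (either via an external
BLAST tabular file or the built-in exact-k-mer mapper); hits are filtered
at the standard thresholds (evalue <= 1e-5, identity >= 95%, query
coverage >= 80%), and each read is then recruited only by the genome with
which it aligns at the highest identity.  Per-genome counts are
normalised to RPKG = (Rx / MG) / Gx — reads per kilobase of genome per
gigabase of metagenome — and depth profiles are Z-normalised per genome
and clustered hierarchically.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .core import GenomeRecord, reverse_complement

__all__ = [
    "RecruitmentHit",
    "parse_blast_tab",
    "filter_hits",
    "competitive_assign",
    "map_reads_simple",
    "rpkg",
    "rpkg_matrix",
    "znormalize",
    "cluster_profiles",
]

MAX_EVALUE = 1e-5
MIN_IDENTITY = 95.0
MIN_COVERAGE = 80.0


@dataclass
class RecruitmentHit:
    read_id: str
    genome_id: str
    percent_identity: float
    query_coverage_percent: float
    alignment_length: int
    score: float
    evalue: Optional[float] = None


def parse_blast_tab(
    path,
    read_lengths: dict[str, int],
    contig_to_genome: dict[str, str],
) -> list[RecruitmentHit]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    Query coverage is 100 * |qend - qstart + 1| / read_length (absolute
    span, so minus-strand query conventions are handled); the subject
    genome is resolved from the subject sequence id via the contig map.
    """
    hits: list[RecruitmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            genome = contig_to_genome.get(sseqid)
            if genome is None:
                raise KeyError(f"{path}: line {lineno}: unknown contig {sseqid!r}")
            read_len = read_lengths.get(qseqid)
            if read_len is None:
                raise KeyError(f"{path}: line {lineno}: unknown read {qseqid!r}")
            span = abs(qend - qstart) + 1
            hits.append(
                RecruitmentHit(
                    read_id=qseqid,
                    genome_id=genome,
                    percent_identity=pident,
                    query_coverage_percent=100.0 * span / read_len,
                    alignment_length=length,
                    score=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def filter_hits(
    hits: Sequence[RecruitmentHit],
    max_evalue: float = MAX_EVALUE,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
) -> list[RecruitmentHit]:
    """Keep hits with evalue <= max_evalue (hits without an evalue pass),
    identity >= min_identity and coverage >= min_coverage (inclusive)."""
    return [
        h
        for h in hits
        if (h.evalue is None or h.evalue <= max_evalue)
        and h.percent_identity >= min_identity
        and h.query_coverage_percent >= min_coverage
    ]


def competitive_assign(hits: Sequence[RecruitmentHit]) -> dict[str, str]:
    """Assign each read to the genome of its highest-identity hit.

    Ties are broken by higher score, then by lexicographically smallest
    genome id; each read maps to at most one genome.
    """
    best: dict[str, RecruitmentHit] = {}
    for h in hits:
        cur = best.get(h.read_id)
        if (
            cur is None
            or h.percent_identity > cur.percent_identity
            or (
                h.percent_identity == cur.percent_identity
                and (
                    h.score > cur.score
                    or (h.score == cur.score and h.genome_id < cur.genome_id)
                )
            )
        ):
            best[h.read_id] = h
    return {rid: h.genome_id for rid, h in best.items()}


def map_reads_simple(
    reads: Sequence[tuple[str, str]],
    genomes: Sequence[GenomeRecord],
    k: int = 21,
    stride: int = 1,
) -> list[RecruitmentHit]:
    """Built-in ungapped mapper: exact k-mer seeding on both strands, full
    ungapped extension of the read, identity over the read length.

    One hit per (read, genome): the best placement found.  Coverage is 100
    for every seeded ungapped hit.  Reads with no seed are unmapped.
    """
    # genome k-mer index: kmer -> list of (genome_idx, seq_idx, pos)
    index: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    seqs: list[list[str]] = []
    for gi, genome in enumerate(genomes):
        strands: list[str] = []
        for _, seq in genome.contigs:
            for s in (seq, reverse_complement(seq)):
                si = len(strands)
                strands.append(s)
                for i in range(len(s) - k + 1):
                    kmer = s[i : i + k]
                    if "N" not in kmer:
                        index[kmer].append((gi, si, i))
        seqs.append(strands)

    hits: list[RecruitmentHit] = []
    for read_id, read in reads:
        if len(read) < k:
            continue
        candidates: set[tuple[int, int, int]] = set()
        for i in range(0, len(read) - k + 1, stride):
            for gi, si, pos in index.get(read[i : i + k], ()):
                candidates.add((gi, si, pos - i))
        best_per_genome: dict[int, float] = {}
        for gi, si, offset in candidates:
            target = seqs[gi][si]
            if offset < 0 or offset + len(read) > len(target):
                continue
            window = target[offset : offset + len(read)]
            if window == read:
                ident = 100.0
            else:
                matches = sum(1 for a, b in zip(read, window) if a == b)
                ident = 100.0 * matches / len(read)
            if ident > best_per_genome.get(gi, -1.0):
                best_per_genome[gi] = ident
        for gi, ident in best_per_genome.items():
            hits.append(
                RecruitmentHit(
                    read_id=read_id,
                    genome_id=genomes[gi].genome_id,
                    percent_identity=ident,
                    query_coverage_percent=100.0,
                    alignment_length=len(read),
                    score=ident * len(read) / 100.0,
                )
            )
    return hits


def rpkg(n_reads: int, genome_length_bp: int, metagenome_size_bp: int) -> float:
    """RPKG = (Rx / MG) / Gx with MG in gigabases and Gx in kilobases:
    reads per kilobase of genome per gigabase of metagenome."""
    if genome_length_bp <= 0 or metagenome_size_bp <= 0:
        raise ValueError("genome and metagenome sizes must be positive")
    return (n_reads / (metagenome_size_bp / 1e9)) / (genome_length_bp / 1e3)


def rpkg_matrix(
    counts: dict[str, dict[str, int]],
    genomes: Sequence[GenomeRecord],
    metagenome_sizes: dict[str, int],
    sample_order: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Genome x sample RPKG matrix from per-sample assigned read counts.

    ``counts`` maps sample_id -> {genome_id: reads assigned}.
    """
    samples = list(sample_order) if sample_order is not None else sorted(counts)
    genome_ids = [g.genome_id for g in genomes]
    length = {g.genome_id: g.genome_length_bp for g in genomes}
    mat = np.zeros((len(genome_ids), len(samples)))
    for j, s in enumerate(samples):
        for i, gid in enumerate(genome_ids):
            mat[i, j] = rpkg(counts[s].get(gid, 0), length[gid], metagenome_sizes[s])
    return mat, genome_ids, samples


def znormalize(matrix: np.ndarray) -> np.ndarray:
    """Per-row Z-normalisation with the sample (n-1) standard deviation;
    constant rows map to all zeros."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 samples per row")
    means = matrix.mean(axis=1, keepdims=True)
    sds = matrix.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(matrix, dtype=float)
    nonconst = (sds > 0).ravel()
    out[nonconst] = (matrix[nonconst] - means[nonconst]) / sds[nonconst]
    return out


def cluster_profiles(
    z_matrix: np.ndarray, genome_ids: Sequence[str], method: str = "complete"
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of genomes by their depth profiles
    (Euclidean distance, complete linkage by default).

    Returns (scipy linkage matrix, leaf order of genome ids, Newick).
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    if z_matrix.shape[0] < 2:
        raise ValueError("need at least 2 genomes")
    order = np.argsort(genome_ids, kind="stable")  # deterministic tie layout
    ids = [genome_ids[i] for i in order]
    mat = z_matrix[order]
    link = linkage(pdist(mat, metric="euclidean"), method=method)
    newick = _to_newick(link, ids)
    leaf_order = _leaf_order(link, ids)
    return link, leaf_order, newick


def _to_newick(link: np.ndarray, ids: Sequence[str]) -> str:
    n = len(ids)
    height = {i: 0.0 for i in range(n)}
    label: dict[int, str] = {i: ids[i] for i in range(n)}
    for row_idx, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        node = n + row_idx
        la = h - height[a]
        lb = h - height[b]
        label[node] = f"({label[a]}:{la:.6g},{label[b]}:{lb:.6g})"
        height[node] = h
    return label[2 * n - 2] + ";"


def _leaf_order(link: np.ndarray, ids: Sequence[str]) -> list[str]:
    n = len(ids)
    children: dict[int, tuple[int, int]] = {}
    for row_idx, (a, b, _, _) in enumerate(link):
        children[n + row_idx] = (int(a), int(b))

    def leaves(node: int) -> list[str]:
        if node < n:
            return [ids[node]]
        a, b = children[node]
        return leaves(a) + leaves(b)

    return leaves(2 * n - 2)
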