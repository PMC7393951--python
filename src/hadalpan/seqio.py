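"""Readers and writers for the plain-text formats the pipeline touches.

FASTA for genomes/CDS/proteins/reads; tab-delimited tables (UTF-8, header
row, no quoting) for gene coordinates, functional annotations and sample
metadata.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Union

from .core import (
    GeneRecord,
    GenomeRecord,
    Role,
    SampleMeta,
    SizeFraction,
    reverse_complement,
    translate_cds,
)

__all__ = [
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "load_gene_table",
    "write_gene_table",
    "load_annotation_table",
    "write_annotation_table",
    "load_sample_table",
    "write_sample_table",
    "extract_cds",
]

PathLike = Union[str, Path]


class FastaFormatError(ValueError):
    pass


def read_fasta(path: PathLike, nucleotide: bool = True) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, sequence).

    Sequences are uppercased; in nucleotide mode U is mapped to T.  The id
    is the first whitespace-delimited token of the header.  Duplicate ids
    and empty header lines are format errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        records.append((name, seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}: empty id on line {lineno}")
                flush()
                name = header.split()[0]
                if name in seen:
                    raise FastaFormatError(f"{path}: duplicate id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"{path}: sequence before first header on line {lineno}"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(path: PathLike, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_cds(genome: GenomeRecord, contig_id: str, start: int, end: int, strand: str) -> str:
    """Extract a CDS from 1-based inclusive forward-strand coordinates."""
    seq = genome.contig(contig_id)
    if start < 1 or end > len(seq):
        raise ValueError(
            f"coordinates {start}..{end} outside contig {contig_id} "
            f"(length {len(seq)})"
        )
    sub = seq[start - 1 : end]
    return reverse_complement(sub) if strand == "-" else sub


def load_gene_table(
    path: PathLike,
    genomes: dict[str, GenomeRecord],
    cds_by_gene: Optional[dict[str, str]] = None,
) -> list[GeneRecord]:
    """Load a gene coordinate table and join each gene to its CDS.

    Expected columns: gene_id, genome_id, contig_id, start, end, strand and
    optionally category.  The CDS is extracted from the genome sequence; if
    ``cds_by_gene`` (e.g. from a CDS FASTA) is given, the extracted CDS is
    verified against it.
    """
    genes: list[GeneRecord] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "genome_id", "contig_id", "start", "end", "strand"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            genome = genomes.get(row["genome_id"])
            if genome is None:
                raise ValueError(f"{path}: unknown genome {row['genome_id']!r}")
            cds = extract_cds(
                genome, row["contig_id"], int(row["start"]), int(row["end"]), row["strand"]
            )
            if cds_by_gene is not None:
                expected = cds_by_gene.get(row["gene_id"])
                if expected is not None and expected != cds:
                    raise ValueError(
                        f"{path}: CDS mismatch for gene {row['gene_id']!r}"
                    )
            category = row.get("category") or None
            genes.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    genome_id=row["genome_id"],
                    contig_id=row["contig_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    cds=cds,
                    protein=translate_cds(cds),
                    category=category,
                )
            )
    return genes


def write_gene_table(path: PathLike, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "genome_id", "contig_id", "start", "end", "strand", "category"])
        for g in genes:
            writer.writerow(
                [g.gene_id, g.genome_id, g.contig_id, g.start, g.end, g.strand, g.category or ""]
            )


def load_annotation_table(path: PathLike) -> dict[str, str]:
    """Load gene_id -> one-letter category."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cat = row.get("category") or ""
            if cat:
                out[row["gene_id"]] = cat
    return out


def write_annotation_table(path: PathLike, annotations: dict[str, str]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "category"])
        for gid, cat in annotations.items():
            writer.writerow([gid, cat])


def load_sample_table(path: PathLike) -> list[SampleMeta]:
    samples: list[SampleMeta] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            samples.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    depth_m=float(row["depth_m"]),
                    size_fraction=SizeFraction(row["size_fraction"]),
                    metagenome_size_bp=int(row["metagenome_size_bp"]),
                )
            )
    return samples


def write_sample_table(path: PathLike, samples: Iterable[SampleMeta]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "depth_m", "size_fraction", "metagenome_size_bp"])
        for s in samples:
            writer.writerow(
                [s.sample_id, s.depth_m, s.size_fraction.value, s.metagenome_size_bp]
            )


def load_genomes_dir(path: PathLike, focal_ids: Optional[set[str]] = None) -> dict[str, GenomeRecord]:
    """Load every ``*.fna``/``*.fasta`` file in a directory as one genome.

    The genome id is the file stem; role is focal when the id is in
    ``focal_ids`` (background otherwise, focal when no set given).
    """
    genomes: dict[str, GenomeRecord] = {}
    for p in sorted(Path(path).iterdir()):
        if p.suffix not in {".fna", ".fasta", ".fa"}:
            continue
        role = Role.FOCAL
        if focal_ids is not None:
            role = Role.FOCAL if p.stem in focal_ids else Role.BACKGROUND
        genomes[p.stem] = GenomeRecord(p.stem, read_fasta(p), role=role)
    return genomes
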