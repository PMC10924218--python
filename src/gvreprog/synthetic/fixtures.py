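"""Toy two-species genome / annotation / read fixtures.

Generates a pair of small single-chromosome genomes (FASTA), matching
exon-level annotations (GTF, 1-based inclusive coordinates) and a FASTQ of
error-free single-end reads copied verbatim from exons. Read names encode
the true species and gene of origin (``read<i>|<species>|<gene_id>``) so
species- and gene-assignment accuracy is measurable exactly.

Genomes are independent random sequences — at the default k-mer sizes a
shared 25-mer between two random 20 kb sequences is vanishingly unlikely —
except for an optional shared segment copied from genome A into genome B
to create deliberately ambiguous reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))


@dataclass
class FixturePaths:
    fasta_a: Path
    fasta_b: Path
    gtf_a: Path
    gtf_b: Path
    fastq: Path


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _place_genes(rng, chrom_length, n_genes, exon_len, reserved):
    """Non-overlapping 2-exon gene intervals avoiding reserved regions."""
    genes = []
    occupied = list(reserved)
    gene_span = 2 * exon_len + 100  # two exons with a 100 bp intron
    for _ in range(20 * n_genes):
        if len(genes) == n_genes:
            break
        start = int(rng.integers(0, chrom_length - gene_span))
        end = start + gene_span
        if any(s < end and start < e for s, e in occupied):
            continue
        occupied.append((start, end))
        exons = [(start, start + exon_len), (end - exon_len, end)]
        genes.append(exons)
    if len(genes) < n_genes:
        raise RuntimeError("could not place genes without overlap")
    genes.sort(key=lambda ex: ex[0][0])
    return genes


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    lines = [f">{name}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)]
    path.write_text("\n".join(lines) + "\n")


def _write_gtf(path: Path, chrom: str, species: str, genes) -> None:
    rows = []
    for i, exons in enumerate(genes):
        gid = f"{species}_gene{i:03d}"
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
        for start0, end0 in exons:
            # GTF is 1-based inclusive
            rows.append(
                "\t".join(
                    [chrom, "sim", "exon", str(start0 + 1), str(end0), ".", "+", ".", attrs]
                )
            )
    path.write_text("\n".join(rows) + "\n")


def write_fixture_genome(
    outdir: str | Path,
    seed: int = 0,
    n_genes_per_species: int = 8,
    chrom_length: int = 20000,
    shared_segment: int = 0,
    n_reads: int = 500,
    read_length: int = 50,
    exon_length: int = 300,
) -> FixturePaths:
    """Write toy genomes, annotations and truth-named exonic reads.

    ``shared_segment`` > 0 copies that many bases from an intergenic region
    of genome A into genome B, making reads drawn from it ambiguous. Reads
    are sampled uniformly over genes and fall entirely within one exon.
    Output is byte-identical for identical arguments.
    """
    gene_span = 2 * exon_length + 100
    if chrom_length < n_genes_per_species * (gene_span + 50) + shared_segment + 100:
        raise ValueError("chrom_length too small for the requested genes")
    if read_length > exon_length:
        raise ValueError("read_length exceeds exon_length")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    seq_a = _random_seq(rng, chrom_length)
    seq_b = _random_seq(rng, chrom_length)
    reserved_a: list[tuple[int, int]] = []
    reserved_b: list[tuple[int, int]] = []
    if shared_segment > 0:
        src = int(rng.integers(0, chrom_length - shared_segment))
        dst = int(rng.integers(0, chrom_length - shared_segment))
        seq_b = seq_b[:dst] + seq_a[src : src + shared_segment] + seq_b[dst + shared_segment :]
        reserved_a.append((src, src + shared_segment))
        reserved_b.append((dst, dst + shared_segment))

    genes_a = _place_genes(rng, chrom_length, n_genes_per_species, exon_length, reserved_a)
    genes_b = _place_genes(rng, chrom_length, n_genes_per_species, exon_length, reserved_b)

    paths = FixturePaths(
        fasta_a=outdir / "speciesA.fa",
        fasta_b=outdir / "speciesB.fa",
        gtf_a=outdir / "speciesA.gtf",
        gtf_b=outdir / "speciesB.gtf",
        fastq=outdir / "reads.fastq",
    )
    # both chromosomes are named chr1: the hybrid builder must disambiguate
    _write_fasta(paths.fasta_a, "chr1", seq_a)
    _write_fasta(paths.fasta_b, "chr1", seq_b)
    _write_gtf(paths.gtf_a, "chr1", "A", genes_a)
    _write_gtf(paths.gtf_b, "chr1", "B", genes_b)

    records = []
    pools = [("A", seq_a, genes_a), ("B", seq_b, genes_b)]
    for i in range(n_reads):
        species, seq, genes = pools[int(rng.integers(0, 2))]
        gi = int(rng.integers(0, len(genes)))
        exon = genes[gi][int(rng.integers(0, 2))]
        start = int(rng.integers(exon[0], exon[1] - read_length + 1))
        read = seq[start : start + read_length]
        name = f"read{i:05d}|{species}|{species}_gene{gi:03d}"
        records.append(f"@{name}\n{read}\n+\n{'I' * read_length}")
    paths.fastq.write_text("\n".join(records) + "\n")
    return paths
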