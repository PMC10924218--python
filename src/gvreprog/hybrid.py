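"""Two-species hybrid reference and species-aware read assignment.

Cross-species NT experiments sequence mouse (or human) nascent transcripts
out of a *Xenopus* oocyte, so every read must first be attributed to a
species. The standard trick is a hybrid reference: both genomes
concatenated, with the second species' chromosome names carrying a
disambiguating prefix (``xla_chr…`` for *X. laevis*).

Read assignment here is a desk-scale unique-k-mer classifier rather than a
spliced aligner: a read whose k-mers (on either strand) are all found in
exactly one species is assigned to it; k-mers found in both species make
the read ambiguous; reads without any k-mer hit are unassigned. Species-
assigned reads whose k-mers all fall within a single gene's exons get that
gene id. Counting mirrors htseq-count union semantics: only uniquely
attributed reads count, and ambiguous/unassigned reads are tallied but
excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyfaidx import Fasta

from gvreprog.containers import CountMatrix

SPECIES_A = "species_A"
SPECIES_B = "species_B"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class GeneRecord:
    """One annotated gene on the hybrid reference (0-based half-open exons)."""

    gene_id: str
    species: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def _parse_gtf_genes(path: str | Path, species: str, chrom_rename) -> dict[str, GeneRecord]:
    """Exon records from a GTF; 1-based inclusive → 0-based half-open."""
    genes: dict[str, GeneRecord] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        attrs = dict(
            (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
            for kv in f[8].rstrip(";").split(";")
            if kv.strip()
        )
        gid = attrs.get("gene_id")
        if gid is None:
            raise ValueError(f"{path}: exon without gene_id")
        chrom = chrom_rename(f[0])
        start0, end0 = int(f[3]) - 1, int(f[4])
        rec = genes.setdefault(
            gid, GeneRecord(gene_id=gid, species=species, chrom=chrom, strand=f[6], exons=[])
        )
        rec.exons.append((start0, end0))
    for rec in genes.values():
        rec.exons.sort()
        if rec.exon_length <= 0:
            raise ValueError(f"gene {rec.gene_id} has zero exon length")
    return genes


@dataclass
class HybridReference:
    """Species-tagged chromosomes plus merged gene annotation."""

    chromosomes: list[tuple[str, str]]  # (name, sequence), A first then prefixed B
    genes: dict[str, GeneRecord]
    prefix: str = "xla_"
    _kmer_index: dict | None = field(default=None, repr=False, compare=False)
    _k: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names not unique after prefixing")
        lengths = {n: len(s) for n, s in self.chromosomes}
        for rec in self.genes.values():
            if rec.chrom not in lengths:
                raise ValueError(f"gene {rec.gene_id} references missing chromosome {rec.chrom}")
            for s, e in rec.exons:
                if not 0 <= s < e <= lengths[rec.chrom]:
                    raise ValueError(f"gene {rec.gene_id} exon ({s},{e}) out of bounds")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def species_of(self, chrom: str) -> str:
        return SPECIES_B if chrom.startswith(self.prefix) else SPECIES_A

    def gene_lengths(self) -> pd.Series:
        return pd.Series(
            {g: rec.exon_length for g, rec in sorted(self.genes.items())}, name="length"
        )

    # -- k-mer index ------------------------------------------------------
    def kmer_index(self, k: int) -> dict[str, tuple[int, frozenset]]:
        """Canonical k-mer → (species bitmask, gene ids whose exons contain it)."""
        if self._kmer_index is not None and self._k == k:
            return self._kmer_index
        if k < 1:
            raise ValueError("k must be >= 1")
        masks: dict[str, int] = {}
        for name, seq in self.chromosomes:
            bit = 2 if self.species_of(name) == SPECIES_B else 1
            su = seq.upper()
            for i in range(len(su) - k + 1):
                km = _canonical(su[i : i + k])
                masks[km] = masks.get(km, 0) | bit
        if not masks:
            raise ValueError("empty reference index")
        gene_hits: dict[str, set] = {}
        chrom_seq = {n: s.upper() for n, s in self.chromosomes}
        for gid, rec in self.genes.items():
            seq = chrom_seq[rec.chrom]
            for s, e in rec.exons:
                for i in range(s, e - k + 1):
                    gene_hits.setdefault(_canonical(seq[i : i + k]), set()).add(gid)
        self._kmer_index = {
            km: (mask, frozenset(gene_hits.get(km, ()))) for km, mask in masks.items()
        }
        self._k = k
        return self._kmer_index


def build_hybrid_reference(
    fasta_a: str | Path,
    fasta_b: str | Path,
    gtf_a: str | Path,
    gtf_b: str | Path,
    prefix: str = "xla_",
) -> HybridReference:
    """Concatenate two genomes into a hybrid reference.

    Species A chromosomes come first in input order, then species B with
    ``prefix`` prepended to each name (``chr1`` → ``xla_chr1``). The merged
    annotation carries a species tag per gene; coordinates are converted to
    0-based half-open internally.
    """
    fa = Fasta(str(fasta_a))
    fb = Fasta(str(fasta_b))
    chroms: list[tuple[str, str]] = []
    a_names = set()
    for name in fa.keys():
        a_names.add(name)
        chroms.append((name, str(fa[name][:])))
    for name in fb.keys():
        new = prefix + name
        if new in a_names:
            raise ValueError(f"chromosome name collision after prefixing: {new}")
        chroms.append((new, str(fb[name][:])))
    if not chroms:
        raise ValueError("empty reference")
    genes = _parse_gtf_genes(gtf_a, SPECIES_A, lambda c: c)
    genes_b = _parse_gtf_genes(gtf_b, SPECIES_B, lambda c: prefix + c)
    dup = set(genes) & set(genes_b)
    if dup:
        raise ValueError(f"gene ids present in both annotations: {sorted(dup)[:5]}")
    genes.update(genes_b)
    return HybridReference(chromosomes=chroms, genes=genes, prefix=prefix)


@dataclass
class ReadAssignment:
    """Per-read species label and, when uniquely exonic, gene id."""

    table: pd.DataFrame  # index read_id; columns: label, gene_id

    def label_counts(self) -> Counter:
        return Counter(self.table["label"])

    @property
    def n_reads(self) -> int:
        return len(self.table)


def _classify_read(seq: str, k: int, index) -> tuple[str, str | None]:
    su = seq.upper()
    if len(su) < k:
        return UNASSIGNED, None
    species_seen = 0
    gene_sets = []
    n_hits = 0
    n_kmers = len(su) - k + 1
    for i in range(n_kmers):
        hit = index.get(_canonical(su[i : i + k]))
        if hit is None:
            continue
        mask, gset = hit
        n_hits += 1
        species_seen |= mask
        gene_sets.append(gset)
    if n_hits == 0:
        return UNASSIGNED, None
    if species_seen == 3:
        return AMBIGUOUS, None
    if n_hits < n_kmers:
        # read not fully contained in either genome
        return UNASSIGNED, None
    label = SPECIES_A if species_seen == 1 else SPECIES_B
    common = frozenset.intersection(*gene_sets) if gene_sets else frozenset()
    if len(common) == 1 and all(len(g) >= 1 for g in gene_sets):
        return label, next(iter(common))
    return label, None


def assign_reads(fastq: str | Path, ref: HybridReference, k: int = 25) -> ReadAssignment:
    """Assign each FASTQ read to a species (and gene where uniquely exonic).

    A read is ``species_A``/``species_B`` when all its k-mers occur in that
    genome only; ``ambiguous`` when any k-mer occurs in both genomes;
    ``unassigned`` when no k-mer (or not every k-mer) is found. Gene ids
    are attached only when every k-mer lies within exactly one common
    gene's exons.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index = ref.kmer_index(k)
    rows = []
    for rec in SeqIO.parse(str(fastq), "fastq"):
        label, gene = _classify_read(str(rec.seq), k, index)
        rows.append((rec.id, label, gene))
    table = pd.DataFrame(rows, columns=["read_id", "label", "gene_id"]).set_index("read_id")
    return ReadAssignment(table=table)


def count_by_gene(
    assignments: dict[str, ReadAssignment],
    ref: HybridReference,
    metadata: pd.DataFrame,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Build a per-gene count matrix from per-sample read assignments.

    Only reads uniquely attributed to one gene are counted; ambiguous and
    unassigned reads are excluded from the matrix but tallied in the
    returned per-sample species summary (species_A, species_B, ambiguous,
    unassigned, total).
    """
    if set(assignments) != set(metadata.index):
        raise ValueError("samples in assignments and metadata differ")
    genes = sorted(ref.genes)
    counts = {}
    summary_rows = {}
    for sample in metadata.index:
        asg = assignments[sample]
        labels = asg.label_counts()
        per_gene = asg.table["gene_id"].dropna().value_counts()
        counts[sample] = per_gene.reindex(genes, fill_value=0).astype(np.int64)
        summary_rows[sample] = {
            SPECIES_A: labels.get(SPECIES_A, 0),
            SPECIES_B: labels.get(SPECIES_B, 0),
            AMBIGUOUS: labels.get(AMBIGUOUS, 0),
            UNASSIGNED: labels.get(UNASSIGNED, 0),
            "total": asg.n_reads,
        }
    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    cm = CountMatrix(counts=matrix, lengths=ref.gene_lengths(), metadata=metadata)
    return cm, pd.DataFrame(summary_rows).T
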