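"""Readers and writers for every external format the pipeline touches.

One canonical in-memory representation per entity; all internal coordinates
are 0-based half-open.  GFF3 and the target-site table use 1-based closed
coordinates in files and are converted exactly once, at this boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed record in an input file; carries the offending line number."""


class ConfigurationError(ValueError):
    """An invalid option (unknown dialect, missing sequence, bad parameter)."""


_ALIGNMENT_COLUMNS = ("chrom", "start", "end", "strand", "sample_id")
_TARGET_COLUMNS = ("transcript_id", "mirna_name", "start", "end", "n_sites")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """One mapped small-RNA read (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open, converted from GFF
    end: int
    strand: str


@dataclass
class GeneAnnotation:
    """Gene set indexed by id and by chromosome."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ParseError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def by_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


@dataclass(frozen=True)
class TargetSiteRecord:
    """A small-RNA/target pairing region on a transcript.

    ``start``/``end`` are 0-based half-open transcript coordinates; files use
    1-based closed.  The miRNA sequence is stored in the RNA alphabet.
    """

    transcript_id: str
    mirna_name: str
    start: int
    end: int
    n_sites: int = 1
    mirna_sequence: str = ""

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not 18 <= length <= 26:
            raise ParseError(
                f"site length {length} outside [18, 26] for "
                f"{self.transcript_id}/{self.mirna_name}"
            )
        if self.mirna_sequence and not 19 <= len(self.mirna_sequence) <= 24:
            raise ParseError(
                f"miRNA length {len(self.mirna_sequence)} outside [19, 24] "
                f"for {self.mirna_name}"
            )
        if self.n_sites < 1:
            raise ParseError("n_sites must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | os.PathLike, dialect: str = "bedlike-tsv") -> list[AlignedRead]:
    """Read aligned reads, preserving file order.

    The ``bedlike-tsv`` dialect has tab-separated columns
    chrom, start, end, strand, sample_id (0-based half-open); ``bam`` is an
    adapter over the same record type (requires pysam).
    """
    if dialect == "bedlike-tsv":
        return _read_alignments_tsv(path)
    if dialect == "bam":
        return _read_alignments_bam(path)
    raise ConfigurationError(f"unknown alignment dialect {dialect!r}")


def _read_alignments_tsv(path: str | os.PathLike) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(parts)}")
            chrom, start_s, end_s, strand, sample_id = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            try:
                reads.append(AlignedRead(chrom, start, end, strand, sample_id))
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return reads


def _read_alignments_bam(path: str | os.PathLike) -> list[AlignedRead]:
    import pysam  # optional dependency; only for the BAM adapter

    sample = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    reads = []
    with pysam.AlignmentFile(os.fspath(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    sample_id=rec.get_tag("RG") if rec.has_tag("RG") else sample,
                )
            )
    return reads


def write_alignments(reads: Iterable[AlignedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_ALIGNMENT_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.sample_id}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | os.PathLike, warn=None) -> GeneAnnotation:
    """Read gene records from a GFF3 file.

    Only ``gene`` features are retained.  1-based closed coordinates are
    converted to 0-based half-open.  A coordinate outside a declared
    ``##sequence-region`` yields a warning (via ``warn``) but the record is
    kept.
    """
    annotation = GeneAnnotation()
    regions: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    regions[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"line {lineno}: expected 9 GFF columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"line {lineno}: invalid interval {start1}..{end1}")
            gene_id = _gff_attribute(attrs, "ID")
            if gene_id is None:
                raise ParseError(f"line {lineno}: gene without ID attribute")
            if chrom in regions and end1 > regions[chrom] and warn is not None:
                warn(f"line {lineno}: {gene_id} extends past {chrom} sequence-region")
            try:
                annotation.add(Gene(gene_id, chrom, start1 - 1, end1, strand))
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return annotation


def _gff_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def write_gff(annotation: GeneAnnotation, path: str | os.PathLike,
              chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in annotation:
            fh.write(
                f"{gene.chrom}\tsirspread\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name->sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def to_rna(seq: str) -> str:
    """Normalize a DNA/RNA string to upper-case RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# target sites
# ---------------------------------------------------------------------------

def read_target_sites(path_tsv: str | os.PathLike,
                      mirna_fasta: str | os.PathLike) -> list[TargetSiteRecord]:
    """Read the target-site table and attach miRNA sequences.

    The TSV carries 1-based closed site coordinates; every miRNA named in
    the table must be present in ``mirna_fasta``.
    """
    mirnas = {name: to_rna(seq) for name, seq in read_fasta(mirna_fasta).items()}
    records: list[TargetSiteRecord] = []
    missing: list[str] = []
    with open(path_tsv) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(parts)}")
            transcript_id, mirna_name, start_s, end_s, n_s = parts
            if mirna_name not in mirnas:
                missing.append(mirna_name)
                continue
            try:
                start1, end1, n_sites = int(start_s), int(end_s), int(n_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer field") from exc
            try:
                records.append(
                    TargetSiteRecord(
                        transcript_id=transcript_id,
                        mirna_name=mirna_name,
                        start=start1 - 1,
                        end=end1,
                        n_sites=n_sites,
                        mirna_sequence=mirnas[mirna_name],
                    )
                )
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if missing:
        raise ConfigurationError(
            "miRNA sequences missing from FASTA: " + ", ".join(sorted(set(missing)))
        )
    return records


def write_target_sites(records: Iterable[TargetSiteRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TARGET_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.transcript_id}\t{r.mirna_name}\t{r.start + 1}\t{r.end}\t{r.n_sites}\n"
            )
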