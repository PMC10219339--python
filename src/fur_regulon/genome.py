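"""Genome annotation model: genes, transcriptional units, promoter windows.

Coordinates follow the GFF3 convention (1-based, inclusive) at the boundary
and an internal 0-based half-open convention (:class:`GenomicInterval`).
A transcriptional unit (TU, operon) is one or more contiguous same-strand
genes transcribed from a shared promoter; its *first gene* is the 5'-most
member in the direction of transcription and carries the promoter whose
occupancy decides whether the whole unit is called a direct target.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: 0-based inclusive start, exclusive end."""

    contig: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in (None, "+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Gene:
    """A gene feature with 1-based inclusive coordinates."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def body_interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start - 1, self.end, self.strand)


@dataclass(frozen=True)
class TranscriptionalUnit:
    """One or more same-strand genes sharing a promoter, ordered 5'->3'."""

    id: str
    gene_ids: tuple[str, ...]
    strand: str
    contig: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise AnnotationError(f"TU {self.id}: no member genes")


@dataclass
class GenomeAnnotation:
    """Genes and transcriptional units of one genome.

    ``tss`` maps gene id to a 1-based transcription start coordinate where
    one is known; position analyses fall back to the start codon otherwise.
    """

    contigs: dict[str, int]
    genes: dict[str, Gene] = field(default_factory=dict)
    tus: dict[str, TranscriptionalUnit] = field(default_factory=dict)
    tss: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            length = self.contigs.get(g.contig)
            if length is None:
                raise AnnotationError(f"gene {g.id}: unknown contig {g.contig}")
            if g.end > length:
                raise AnnotationError(
                    f"gene {g.id}: end {g.end} beyond contig {g.contig} "
                    f"length {length}"
                )

    @property
    def tu_of_gene(self) -> dict[str, str]:
        return {gid: tu.id for tu in self.tus.values() for gid in tu.gene_ids}

    def genes_on(self, contig: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.contig == contig),
            key=lambda g: (g.start, g.end, g.id),
        )


def _validate_gff_lines(text: str) -> None:
    """Cheap structural validation so errors can name the offending line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"GFF line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        if fields[2] != "gene":
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationError(f"GFF line {lineno}: malformed coordinate") from exc
        if end < start:
            raise AnnotationError(
                f"GFF line {lineno}: gene end {end} < start {start}"
            )
        if "ID=" not in fields[8]:
            raise AnnotationError(f"GFF line {lineno}: gene feature without ID")


def read_annotation(
    gff: str | Path | _io.TextIOBase,
    contig_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Parse gene features from a GFF3 stream into a :class:`GenomeAnnotation`.

    Only ``gene`` features are consumed; child features (CDS, exon, ...) and
    other types are ignored. ``contig_lengths`` may be omitted when the GFF
    carries ``##sequence-region`` pragmas.
    """
    if isinstance(gff, (str, Path)):
        text = Path(gff).read_text()
    else:
        text = gff.read()
    _validate_gff_lines(text)

    lengths: dict[str, int] = dict(contig_lengths or {})
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                lengths.setdefault(parts[1], int(parts[3]))

    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, Gene] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in genes:
            raise AnnotationError(f"duplicate gene id {gid}")
        product = feat.attributes.get("product", [None])[0]
        genes[gid] = Gene(
            id=gid, contig=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand, product=product,
        )
    if not lengths:
        # fall back to the right-most feature end per contig
        for g in genes.values():
            lengths[g.contig] = max(lengths.get(g.contig, 0), g.end)
    return GenomeAnnotation(contigs=lengths, genes=genes)


def _order_members(genes: Sequence[Gene], strand: str) -> tuple[str, ...]:
    ordered = sorted(genes, key=lambda g: g.start)
    if strand == "-":
        ordered = ordered[::-1]
    return tuple(g.id for g in ordered)


def _tu_from_members(tu_id: str, members: Sequence[Gene]) -> TranscriptionalUnit:
    strands = {g.strand for g in members}
    if len(strands) != 1:
        raise AnnotationError(f"TU {tu_id}: members on mixed strands")
    contigs = {g.contig for g in members}
    if len(contigs) != 1:
        raise AnnotationError(f"TU {tu_id}: members on multiple contigs")
    strand = strands.pop()
    contig = contigs.pop()
    span = GenomicInterval(
        contig, min(g.start for g in members) - 1, max(g.end for g in members), strand
    )
    return TranscriptionalUnit(
        id=tu_id, gene_ids=_order_members(members, strand),
        strand=strand, contig=contig, span=span,
    )


def build_transcriptional_units(
    annotation: GenomeAnnotation,
    tu_table: Iterable[tuple[str, str]] | None = None,
    max_gap_bp: int = 50,
) -> GenomeAnnotation:
    """Attach transcriptional units, from a curated table or by inference.

    With ``tu_table`` (pairs of ``(unit_id, gene_id)`` in member order) the
    listed units are taken verbatim. Without one, consecutive same-strand
    genes whose intergenic gap is at most ``max_gap_bp`` are grouped — a
    standard operon-adjacency heuristic; a curated table is preferred when
    available.
    """
    tus: dict[str, TranscriptionalUnit] = {}
    if tu_table is not None:
        members: dict[str, list[Gene]] = {}
        for unit_id, gene_id in tu_table:
            if gene_id not in annotation.genes:
                raise AnnotationError(f"TU table names unknown gene {gene_id}")
            members.setdefault(unit_id, []).append(annotation.genes[gene_id])
        for unit_id, genes in members.items():
            tus[unit_id] = _tu_from_members(unit_id, genes)
    else:
        if max_gap_bp < 0:
            raise AnnotationError("max_gap_bp must be >= 0")
        for contig in annotation.contigs:
            run: list[Gene] = []
            for gene in annotation.genes_on(contig):
                if run and (
                    gene.strand != run[-1].strand
                    or gene.start - run[-1].end - 1 > max_gap_bp
                ):
                    tu = _tu_from_members(f"tu_{run[0].id}", run)
                    tu = replace(tu, id=f"tu_{tu.gene_ids[0]}")
                    tus[tu.id] = tu
                    run = []
                run.append(gene)
            if run:
                tu = _tu_from_members(f"tu_{run[0].id}", run)
                tu = replace(tu, id=f"tu_{tu.gene_ids[0]}")
                tus[tu.id] = tu
    annotation.tus = tus
    return annotation


def first_gene(tu: TranscriptionalUnit, annotation: GenomeAnnotation) -> Gene:
    """The 5'-most member gene in transcription direction.

    Re-derived from coordinates rather than trusting the stored order:
    leftmost start for ``+`` units, rightmost end for ``-`` units.
    """
    members = [annotation.genes[g] for g in tu.gene_ids]
    if tu.strand == "+":
        return min(members, key=lambda g: g.start)
    return max(members, key=lambda g: g.end)


def promoter_window(
    gene: Gene, width_bp: int, annotation: GenomeAnnotation
) -> GenomicInterval | None:
    """The ``width_bp`` window immediately upstream of the start codon.

    Truncated at contig boundaries; returns None when fully truncated
    (a gene starting at the very contig edge).
    """
    if width_bp <= 0:
        raise AnnotationError("width_bp must be positive")
    contig_len = annotation.contigs[gene.contig]
    if gene.strand == "+":
        end = gene.start - 1  # 0-based position of the start codon
        start = max(0, end - width_bp)
    else:
        start = gene.end
        end = min(contig_len, start + width_bp)
    if start >= end:
        return None
    return GenomicInterval(gene.contig, start, end, gene.strand)


def tss_position(gene: Gene, annotation: GenomeAnnotation) -> int:
    """0-based anchor for signed site positions: TSS if known, else start codon."""
    t = annotation.tss.get(gene.id)
    if t is not None:
        return t - 1
    return gene.start - 1 if gene.strand == "+" else gene.end - 1


def read_fasta(fasta: str | Path | _io.TextIOBase) -> dict[str, str]:
    """Load contig sequences (uppercased) keyed by record id."""
    handle = open(fasta) if isinstance(fasta, (str, Path)) else fasta
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if isinstance(fasta, (str, Path)):
            handle.close()


def extract_sequences(
    fasta: str | Path | _io.TextIOBase | Mapping[str, str],
    intervals: Sequence[GenomicInterval],
) -> list[str]:
    """Slice interval sequences; minus-strand intervals are reverse-complemented."""
    contigs = fasta if isinstance(fasta, Mapping) else read_fasta(fasta)
    out: list[str] = []
    for iv in intervals:
        if iv.contig not in contigs:
            raise AnnotationError(f"interval on unknown contig {iv.contig}")
        seq = contigs[iv.contig][iv.start : iv.end].upper()
        if iv.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append(seq)
    return out
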