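"""Transcript models: GTF I/O, intron derivation, annotation summaries.

The in-memory coordinate convention is 0-based half-open throughout the
package; GTF on disk is 1-based inclusive. Length arithmetic is therefore
always ``end - start``.

A :class:`TranscriptomeAnnotation` is the substrate for every downstream
analysis: gene -> transcript -> ordered exons, with introns derived as the
gaps between consecutive exons of one transcript.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "Exon",
    "Intron",
    "Transcript",
    "Gene",
    "TranscriptomeAnnotation",
    "AnnotationSummary",
    "GtfParseError",
    "AnnotationValidationError",
    "read_gtf",
    "write_gtf",
    "derive_introns",
    "summarize_annotation",
    "gc_content",
    "expression_percentile",
]


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class AnnotationValidationError(ValueError):
    """An annotation violates a structural invariant (e.g. overlapping exons)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise AnnotationValidationError("interval contig must be non-empty")
        if not self.start < self.end:
            raise AnnotationValidationError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    transcript_id: str

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Intron:
    """Gap between two consecutive exons of one transcript."""

    interval: GenomicInterval
    flanking_exon_ids: tuple[str, str]

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[Exon]
    fpkm: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: no exons"
            )
        contigs = {e.interval.contig for e in self.exons}
        if len(contigs) > 1:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: exons span contigs {sorted(contigs)}"
            )
        strands = {e.interval.strand for e in self.exons}
        if len(strands) > 1:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: exons on mixed strands"
            )
        self.exons.sort(key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def contig(self) -> str:
        return self.exons[0].interval.contig

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def length(self) -> int:
        """Mature (exonic) length in bp."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class Gene:
    gene_id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationValidationError(f"gene {self.gene_id}: no transcripts")
        contigs = {t.contig for t in self.transcripts}
        if len(contigs) > 1:
            raise AnnotationValidationError(
                f"gene {self.gene_id}: transcripts span contigs {sorted(contigs)}"
            )

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.contig, start, end, self.strand)


@dataclass
class TranscriptomeAnnotation:
    """Ordered collection of genes; iteration order is insertion order."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self:
            yield from gene.transcripts

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def transcript_count(self) -> int:
        return sum(len(g.transcripts) for g in self)


@dataclass
class AnnotationSummary:
    gene_count: int
    transcript_count: int
    exon_count: int
    intron_count: int
    mean_gene_span_bp: float
    mean_transcript_length_bp: float
    mean_exon_count: float
    mean_exon_length_bp: float
    mean_intron_length_bp: float
    transcribed_footprint_bp: int
    exonic_footprint_bp: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tvalue"]
        for k, v in self.to_dict().items():
            lines.append(f"{k}\t{v}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> TranscriptomeAnnotation:
    """Read exon features from a GTF file into an annotation.

    Coordinates are converted from 1-based inclusive (on disk) to 0-based
    half-open. Only ``exon`` features are consumed; other feature types are
    ignored. Exons are grouped by ``gene_id``/``transcript_id`` attributes.

    Raises
    ------
    GtfParseError
        On a malformed line, naming its line number.
    AnnotationValidationError
        If a transcript has overlapping exons or spans contigs/strands.
    """
    path = Path(path)
    # transcript_id -> (gene_id, [Exon]); insertion-ordered
    by_transcript: dict[str, tuple[str, list[Exon]]] = {}
    gene_order: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"line {lineno}: bad coordinates {start1}..{end1} (1-based inclusive)"
                )
            attrs = _parse_attributes(attr_s, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: attributes must contain gene_id and transcript_id"
                )
            tid = attrs["transcript_id"]
            gid = attrs["gene_id"]
            interval = GenomicInterval(contig, start1 - 1, end1, strand)
            if tid not in by_transcript:
                by_transcript[tid] = (gid, [])
            elif by_transcript[tid][0] != gid:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} assigned to multiple genes"
                )
            by_transcript[tid][1].append(Exon(interval, tid))

    genes: dict[str, list[Transcript]] = {}
    for tid, (gid, exons) in by_transcript.items():
        tx = Transcript(tid, gid, exons)
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(tx)

    annotation = TranscriptomeAnnotation()
    for gid in gene_order:
        annotation.genes[gid] = Gene(gid, genes[gid])
    return annotation


def write_gtf(annotation: TranscriptomeAnnotation, path: str | Path) -> None:
    """Write exon features as GTF (1-based inclusive coordinates)."""
    path = Path(path)
    lines = ["#gtf produced by stemtx; exon features only"]
    for gene in annotation:
        for tx in gene.transcripts:
            for exon in tx.exons:
                iv = exon.interval
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                lines.append(
                    "\t".join(
                        (
                            iv.contig,
                            "stemtx",
                            "exon",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        )
                    )
                )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Derived structure and summaries
# ---------------------------------------------------------------------------

def derive_introns(transcript: Transcript) -> list[Intron]:
    """Introns of a transcript: the gaps between consecutive exons.

    A transcript with n exons yields n-1 introns; a single-exon transcript
    yields none.
    """
    introns = []
    for prev, nxt in zip(transcript.exons, transcript.exons[1:]):
        introns.append(
            Intron(
                GenomicInterval(
                    transcript.contig, prev.end, nxt.start, transcript.strand
                ),
                (transcript.transcript_id, transcript.transcript_id),
            )
        )
    return introns


def _union_length(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total bp covered by a set of (contig, start, end) intervals."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in intervals:
        by_contig.setdefault(contig, []).append((start, end))
    total = 0
    for spans in by_contig.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start
    return total


def summarize_annotation(annotation: TranscriptomeAnnotation) -> AnnotationSummary:
    """Genome-wide counts, mean lengths, and genomic footprints.

    Transcript length is exonic (mature) length. The transcribed footprint is
    the union of gene spans (introns included); the exonic footprint is the
    union of exon intervals. Exon and intron counts are totals over
    transcripts, i.e. an exon shared by two isoforms counts twice.
    """
    if len(annotation) == 0:
        raise ValueError("cannot summarize an empty annotation")
    gene_spans = []
    tx_lengths = []
    exon_lengths = []
    intron_lengths = []
    exon_counts = []
    exon_intervals = []
    for gene in annotation:
        span = gene.span
        gene_spans.append(span.length)
        for tx in gene.transcripts:
            tx_lengths.append(tx.length)
            exon_counts.append(len(tx.exons))
            for exon in tx.exons:
                exon_lengths.append(exon.length)
                exon_intervals.append((exon.interval.contig, exon.start, exon.end))
            for intron in derive_introns(tx):
                intron_lengths.append(intron.length)
    gene_span_intervals = [
        (g.contig, g.span.start, g.span.end) for g in annotation
    ]
    return AnnotationSummary(
        gene_count=len(annotation),
        transcript_count=len(tx_lengths),
        exon_count=len(exon_lengths),
        intron_count=len(intron_lengths),
        mean_gene_span_bp=float(sum(gene_spans) / len(gene_spans)),
        mean_transcript_length_bp=float(sum(tx_lengths) / len(tx_lengths)),
        mean_exon_count=float(sum(exon_counts) / len(exon_counts)),
        mean_exon_length_bp=float(sum(exon_lengths) / len(exon_lengths)),
        mean_intron_length_bp=(
            float(sum(intron_lengths) / len(intron_lengths)) if intron_lengths else 0.0
        ),
        transcribed_footprint_bp=_union_length(gene_span_intervals),
        exonic_footprint_bp=_union_length(exon_intervals),
    )


def gc_content(sequences: Sequence[str]) -> float:
    """Fraction (G+C)/(A+C+G+T) over a set of sequences; N is ignored.

    Ambiguity codes other than N raise; a denominator of zero raises.
    """
    gc = 0
    acgt = 0
    for seq in sequences:
        for base in seq.upper():
            if base in "GC":
                gc += 1
                acgt += 1
            elif base in "AT":
                acgt += 1
            elif base == "N":
                continue
            else:
                raise ValueError(f"unexpected base {base!r}")
    if acgt == 0:
        raise ValueError("no informative (A/C/G/T) bases")
    return gc / acgt


def expression_percentile(fpkm_values: Sequence[float], threshold: float) -> float:
    """Percentile of the expression distribution bounded by ``threshold``.

    Returns 100 x fraction of values <= threshold (inclusive), so a cutoff of
    "FPKM > t" retains the values above the returned percentile.
    """
    values = list(fpkm_values)
    if not values:
        raise ValueError("empty FPKM list")
    at_or_below = sum(1 for v in values if v <= threshold)
    return 100.0 * at_or_below / len(values)
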