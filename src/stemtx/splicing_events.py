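"""Alternative-splicing event detection and reading-frame analysis.

Events are detected purely from transcript models (no read evidence): two
isoforms of one gene that differ in their exon/intron structure between
shared splice sites define an event. Five classes are recognised:

* cassette          — an internal exon included in one isoform and cleanly
                      skipped by a single junction in another
* retained_intron   — an intron of one isoform fully contained in a single
                      exon of another whose boundaries match the flanking
                      exons' outer boundaries
* mutually_exclusive — two non-overlapping internal exons between shared
                      flanks; every isoform spanning those flanks carries
                      exactly one of the two
* alt5ss / alt3ss   — two isoforms share one intron boundary (the acceptor
                      or the donor, respectively) and differ at the other;
                      donor/acceptor roles follow the strand

Alternative transcription start/polyadenylation sites are not splicing
events: cassette and mutually-exclusive calls are restricted to internal
exons, and alternative-splice-site calls require the variable segment to be
exonic in the long isoform.

Frame analysis classifies a variable region by its length modulo 3
(phase 0 = in-frame); the cassette-vs-constitutive frame bias is tested with
a 2x2 chi-square without continuity correction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from scipy import stats

from .transcript_models import (
    AnnotationValidationError,
    Exon,
    Gene,
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
    derive_introns,
)

__all__ = [
    "EVENT_KINDS",
    "SpliceEvent",
    "FrameClass",
    "EventSummary",
    "detect_events",
    "detect_events_annotation",
    "classify_frame",
    "constitutive_exons",
    "frame_bias_test",
    "summarize_events",
]

EVENT_KINDS = ("cassette", "retained_intron", "mutually_exclusive", "alt5ss", "alt3ss")


@dataclass
class SpliceEvent:
    kind: str
    gene_id: str
    contig: str
    strand: str
    core: tuple[tuple[int, int], ...]  # one interval; two for mutually_exclusive
    flanks: tuple[int, int]  # shared splice-site coordinates anchoring the event
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]

    @property
    def key(self) -> tuple:
        """Gene-wide deduplication key: kind + sorted core coordinates + strand."""
        return (self.kind, tuple(sorted(self.core)), self.strand)

    @property
    def core_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.contig, s, e, self.strand) for s, e in self.core]


@dataclass(frozen=True)
class FrameClass:
    length_bp: int
    phase: int
    in_frame: bool

    @property
    def codons(self) -> int | None:
        return self.length_bp // 3 if self.in_frame else None


@dataclass
class EventSummary:
    event_counts: dict[str, int]
    gene_counts: dict[str, int]

    @property
    def total_events(self) -> int:
        return sum(self.event_counts.values())

    @property
    def total_genes(self) -> int:
        return self._total_genes

    _total_genes: int = 0

    def to_dict(self) -> dict:
        return {
            "events": dict(self.event_counts),
            "genes": dict(self.gene_counts),
            "total_events": self.total_events,
            "total_genes_with_event": self.total_genes,
        }


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _exon_tuples(tx: Transcript) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.exons]


def _intron_tuples(tx: Transcript) -> list[tuple[int, int]]:
    return [(i.start, i.end) for i in derive_introns(tx)]


def _cassette_pairs(a: Transcript, b: Transcript):
    """Cassette events with inclusion isoform ``a`` and skipping isoform ``b``."""
    b_introns = set(_intron_tuples(b))
    events = []
    exons = a.exons
    for i in range(1, len(exons) - 1):
        donor = exons[i - 1].end  # upstream-flank donor (+ orientation)
        acceptor = exons[i + 1].start
        if (donor, acceptor) in b_introns:
            events.append(
                (
                    "cassette",
                    ((exons[i].start, exons[i].end),),
                    (donor, acceptor),
                    a.transcript_id,
                    b.transcript_id,
                )
            )
    return events


def _retained_intron_pairs(a: Transcript, b: Transcript):
    """Retained-intron events: intron of ``a`` retained within one exon of ``b``."""
    b_exons = set(_exon_tuples(b))
    events = []
    for j, intron in enumerate(derive_introns(a)):
        outer = (a.exons[j].start, a.exons[j + 1].end)
        if outer in b_exons:
            events.append(
                (
                    "retained_intron",
                    ((intron.start, intron.end),),
                    (intron.start, intron.end),
                    b.transcript_id,  # inclusion = intron present in mature transcript
                    a.transcript_id,
                )
            )
    return events


def _alt_ss_pairs(a: Transcript, b: Transcript):
    """Alternative 5'/3' splice-site events between two isoforms.

    Two introns sharing exactly one boundary differ at the other; the
    variable segment must lie inside the corresponding exon of the
    longer-exon isoform (otherwise the pair reflects a different structure,
    e.g. exon skipping). Kind assignment respects strand: the intron start
    boundary is the donor on '+' and the acceptor on '-'.
    """
    events = []
    a_introns = _intron_tuples(a)
    b_introns = _intron_tuples(b)
    a_exon_by_end = {e.end: e for e in a.exons}
    a_exon_by_start = {e.start: e for e in a.exons}
    b_exon_by_end = {e.end: e for e in b.exons}
    b_exon_by_start = {e.start: e for e in b.exons}
    plus = a.strand != "-"
    for s1, e1 in a_introns:
        for s2, e2 in b_introns:
            if e1 == e2 and s1 != s2:
                # variable left (intron start) boundary
                lo, hi = min(s1, s2), max(s1, s2)
                # exon ending at the larger boundary belongs to the isoform
                # whose intron starts there; segment [lo, hi) must be exonic
                exon = a_exon_by_end.get(hi) if s1 == hi else b_exon_by_end.get(hi)
                if exon is None or exon.start > lo:
                    continue
                kind = "alt5ss" if plus else "alt3ss"
                incl, excl = (
                    (a.transcript_id, b.transcript_id)
                    if s1 == hi
                    else (b.transcript_id, a.transcript_id)
                )
                events.append((kind, ((lo, hi),), (e1, e1), incl, excl))
            elif s1 == s2 and e1 != e2:
                lo, hi = min(e1, e2), max(e1, e2)
                exon = a_exon_by_start.get(lo) if e1 == lo else b_exon_by_start.get(lo)
                if exon is None or exon.end < hi:
                    continue
                kind = "alt3ss" if plus else "alt5ss"
                incl, excl = (
                    (a.transcript_id, b.transcript_id)
                    if e1 == lo
                    else (b.transcript_id, a.transcript_id)
                )
                events.append((kind, ((lo, hi),), (s1, s1), incl, excl))
    return events


def _mutually_exclusive_events(gene: Gene):
    """Gene-level mutually-exclusive exon detection.

    Candidate exons are internal exons grouped by their shared flank splice
    sites (upstream donor, downstream acceptor). A pair of non-overlapping
    candidates (E1 < E2) is mutually exclusive iff every isoform spanning
    those flanks includes exactly one of the two.
    """
    candidates: dict[tuple[int, int], dict[tuple[int, int], set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for tx in gene.transcripts:
        exons = tx.exons
        for i in range(1, len(exons) - 1):
            flanks = (exons[i - 1].end, exons[i + 1].start)
            candidates[flanks][(exons[i].start, exons[i].end)].add(tx.transcript_id)

    # isoforms spanning a flank pair: contain an exon ending at the donor and
    # a downstream exon starting at the acceptor
    def spanning(flanks: tuple[int, int]) -> set[str]:
        donor, acceptor = flanks
        out = set()
        for tx in gene.transcripts:
            ends = {e.end for e in tx.exons}
            starts = {e.start for e in tx.exons}
            if donor in ends and acceptor in starts:
                out.add(tx.transcript_id)
        return out

    exon_sets = {
        tx.transcript_id: set(_exon_tuples(tx)) for tx in gene.transcripts
    }
    events = []
    for flanks, exon_map in candidates.items():
        exon_list = sorted(exon_map)
        span_tx = spanning(flanks)
        for i in range(len(exon_list)):
            for j in range(i + 1, len(exon_list)):
                e1, e2 = exon_list[i], exon_list[j]
                if e1[1] > e2[0]:  # overlapping
                    continue
                # inclusion is exon membership among flank-spanning isoforms
                with_e1 = {t for t in span_tx if e1 in exon_sets[t]}
                with_e2 = {t for t in span_tx if e2 in exon_sets[t]}
                if not with_e1 or not with_e2:
                    continue
                if with_e1 & with_e2:
                    continue  # some isoform includes both
                if span_tx - (with_e1 | with_e2):
                    continue  # some spanning isoform includes neither
                events.append(
                    (
                        "mutually_exclusive",
                        (e1, e2),
                        flanks,
                        frozenset(with_e1),
                        frozenset(with_e2),
                    )
                )
    return events


def _complex_pairs(a: Transcript, b: Transcript, alt_cores: set[tuple[int, int]]):
    """Diagnostic channel: overlapping exon pairs with both boundaries different
    that do not reduce to an alternative splice-site event."""
    events = []
    for ea in a.exons:
        for eb in b.exons:
            if not ea.interval.overlaps(eb.interval):
                continue
            if ea.start == eb.start or ea.end == eb.end:
                continue
            lo = min(ea.start, eb.start)
            hi = max(ea.end, eb.end)
            if any(lo <= s and e <= hi for s, e in alt_cores):
                continue
            events.append(
                (
                    "complex",
                    ((lo, hi),),
                    (lo, hi),
                    a.transcript_id,
                    b.transcript_id,
                )
            )
    return events


def detect_events(gene: Gene, emit_complex: bool = False) -> list[SpliceEvent]:
    """Detect and deduplicate alternative-splicing events in one gene.

    Events are extracted from every ordered isoform pair (mutually-exclusive
    exons are resolved gene-wide), then deduplicated by
    (kind, core coordinates, strand); inclusion/exclusion supports are merged
    across pairs. Genes with fewer than two isoforms yield no events.

    With ``emit_complex`` the diagnostic "complex" channel (overlapping exon
    pairs with both boundaries different that fit no class) is appended.
    """
    for tx in gene.transcripts:
        tx.validate()
    if len(gene.transcripts) < 2:
        return []
    contig = gene.contig
    strand = gene.strand

    raw: list[tuple] = []
    txs = gene.transcripts
    for a in txs:
        for b in txs:
            if a.transcript_id == b.transcript_id:
                continue
            raw.extend(_cassette_pairs(a, b))
            raw.extend(_retained_intron_pairs(a, b))
            raw.extend(_alt_ss_pairs(a, b))

    merged: dict[tuple, SpliceEvent] = {}
    for kind, core, flanks, incl, excl in raw:
        incl_set = frozenset([incl]) if isinstance(incl, str) else frozenset(incl)
        excl_set = frozenset([excl]) if isinstance(excl, str) else frozenset(excl)
        key = (kind, tuple(sorted(core)), strand)
        if key in merged:
            ev = merged[key]
            ev.inclusion_transcripts = ev.inclusion_transcripts | incl_set
            ev.exclusion_transcripts = ev.exclusion_transcripts | excl_set
        else:
            merged[key] = SpliceEvent(
                kind, gene.gene_id, contig, strand, core, flanks, incl_set, excl_set
            )

    for kind, core, flanks, incl, excl in _mutually_exclusive_events(gene):
        key = (kind, tuple(sorted(core)), strand)
        if key not in merged:
            merged[key] = SpliceEvent(
                kind, gene.gene_id, contig, strand, core, flanks, incl, excl
            )

    events = sorted(
        merged.values(), key=lambda e: (tuple(sorted(e.core)), e.kind)
    )

    if emit_complex:
        alt_cores = {c for e in events for c in e.core if e.kind in ("alt5ss", "alt3ss")}
        cxs: dict[tuple, SpliceEvent] = {}
        for a in txs:
            for b in txs:
                if a.transcript_id >= b.transcript_id:
                    continue
                for kind, core, flanks, incl, excl in _complex_pairs(a, b, alt_cores):
                    key = (kind, tuple(sorted(core)), strand)
                    if key in cxs:
                        ev = cxs[key]
                        ev.inclusion_transcripts = ev.inclusion_transcripts | {incl}
                        ev.exclusion_transcripts = ev.exclusion_transcripts | {excl}
                    else:
                        cxs[key] = SpliceEvent(
                            kind,
                            gene.gene_id,
                            contig,
                            strand,
                            core,
                            flanks,
                            frozenset([incl]),
                            frozenset([excl]),
                        )
        events.extend(sorted(cxs.values(), key=lambda e: tuple(sorted(e.core))))
    return events


def detect_events_annotation(
    annotation: TranscriptomeAnnotation, emit_complex: bool = False
) -> list[SpliceEvent]:
    """Run :func:`detect_events` over every gene of an annotation."""
    events: list[SpliceEvent] = []
    for gene in annotation:
        events.extend(detect_events(gene, emit_complex=emit_complex))
    return events


# ---------------------------------------------------------------------------
# Reading frame
# ---------------------------------------------------------------------------

def classify_frame(length_bp: int) -> FrameClass:
    """Classify a variable region by reading-frame phase.

    Phase = length mod 3. Phase 0 regions preserve the downstream reading
    frame (in-frame); phases 1 and 2 shift it.
    """
    if length_bp < 1:
        raise ValueError(f"length must be positive, got {length_bp}")
    phase = length_bp % 3
    return FrameClass(length_bp=length_bp, phase=phase, in_frame=phase == 0)


def constitutive_exons(annotation: TranscriptomeAnnotation) -> list[Exon]:
    """Internal exons shared by every isoform of their gene.

    An exon qualifies if it is internal (not first or last) in some
    transcript and its exact coordinates appear in every isoform of the
    gene; for single-isoform genes the all-isoform condition is vacuous, so
    every internal exon qualifies. Each qualifying coordinate pair is
    reported once per gene.
    """
    out: list[Exon] = []
    for gene in annotation:
        exon_sets = [set(_exon_tuples(tx)) for tx in gene.transcripts]
        common = set.intersection(*exon_sets)
        seen: set[tuple[int, int]] = set()
        for tx in gene.transcripts:
            for i in range(1, len(tx.exons) - 1):
                coords = (tx.exons[i].start, tx.exons[i].end)
                if coords in common and coords not in seen:
                    seen.add(coords)
                    out.append(tx.exons[i])
    return out


def frame_bias_test(
    cassette_lengths: list[int], constitutive_lengths: list[int]
) -> dict:
    """Chi-square test for frame-preservation bias, cassette vs constitutive.

    Builds the 2x2 table (in-frame/frameshift x cassette/constitutive) and
    applies Pearson's chi-square without continuity correction (df = 1).
    Returns the statistic, p-value, the in-frame fraction of each group, and
    a ``low_expected`` flag set when any expected cell is below 1.
    """
    if not cassette_lengths or not constitutive_lengths:
        raise ValueError("both exon-length lists must be non-empty")
    a = sum(1 for l in cassette_lengths if classify_frame(l).in_frame)
    b = len(cassette_lengths) - a
    c = sum(1 for l in constitutive_lengths if classify_frame(l).in_frame)
    d = len(constitutive_lengths) - c
    table = [[a, b], [c, d]]
    if (a + c) == 0 or (b + d) == 0:
        chi2, p = 0.0, 1.0
        expected_min = 0.0
    else:
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        expected_min = float(expected.min())
    return {
        "chi2": float(chi2),
        "p": float(p),
        "frame_fraction_cassette": a / len(cassette_lengths),
        "frame_fraction_constitutive": c / len(constitutive_lengths),
        "table": table,
        "low_expected": expected_min < 1.0,
    }


def summarize_events(events: list[SpliceEvent]) -> EventSummary:
    """Per-kind event and distinct-gene counts over deduplicated events.

    Diagnostic 'complex' events are excluded from the five-class summary.
    """
    event_counts = {k: 0 for k in EVENT_KINDS}
    genes_per_kind: dict[str, set[str]] = {k: set() for k in EVENT_KINDS}
    all_genes: set[str] = set()
    for ev in events:
        if ev.kind not in event_counts:
            continue
        event_counts[ev.kind] += 1
        genes_per_kind[ev.kind].add(ev.gene_id)
        all_genes.add(ev.gene_id)
    summary = EventSummary(
        event_counts=event_counts,
        gene_counts={k: len(v) for k, v in genes_per_kind.items()},
    )
    summary._total_genes = len(all_genes)
    return summary


def write_events_tsv(events: list[SpliceEvent], path) -> None:
    """Events as a BED-like TSV (0-based half-open core coordinates)."""
    from pathlib import Path

    lines = [
        "contig\tstart\tend\tevent_id\tkind\tstrand\tgene_id\t"
        "inclusion_transcripts\texclusion_transcripts"
    ]
    for idx, ev in enumerate(events):
        start = min(s for s, _ in ev.core)
        end = max(e for _, e in ev.core)
        lines.append(
            "\t".join(
                (
                    ev.contig,
                    str(start),
                    str(end),
                    f"event_{idx:06d}",
                    ev.kind,
                    ev.strand,
                    ev.gene_id,
                    ",".join(sorted(ev.inclusion_transcripts)),
                    ",".join(sorted(ev.exclusion_transcripts)),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
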