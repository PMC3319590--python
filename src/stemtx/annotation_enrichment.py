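"""Functional annotation filters, GO transfer, and category enrichment.

Protein-level homology calls accept alignments at e-value <= 1e-10; domain
hits (Pfam/Smart style) are accepted at e-value <= 1e-3 when at least 80%
of the domain length maps to the transcript. GO terms are transferred flat
from accepted domains (no ancestor propagation). Category enrichment
between a target and a control transcript set uses a 2x2 chi-square without
continuity correction, Bonferroni-adjusted over the categories tested, with
a flagged Fisher's-exact fallback when an expected cell drops below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .orthology_conservation import AlignmentHit, _rank

__all__ = [
    "DomainHit",
    "GOAssignment",
    "EnrichmentResult",
    "filter_homolog_hits",
    "filter_domain_hits",
    "transfer_go",
    "domain_frequency",
    "go_enrichment",
    "read_domain_hits",
    "read_go_map",
]


@dataclass(frozen=True)
class DomainHit:
    transcript_id: str
    domain_id: str
    evalue: float
    domain_coverage: float  # aligned span / full domain length
    source: str = "Pfam"

    def __post_init__(self):
        if not 0.0 <= self.domain_coverage <= 1.0:
            raise ValueError(
                f"coverage must be within [0, 1], got {self.domain_coverage}"
            )


@dataclass(frozen=True)
class GOAssignment:
    transcript_id: str
    go_terms: frozenset[str]
    source_domains: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    count_target: int
    count_control: int
    chi2: float
    p_raw: float
    p_bonferroni: float
    fisher_fallback: bool = False


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a domain-hit TSV: transcript_id, domain_id, source, evalue, coverage."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainHit(str(r.transcript_id), str(r.domain_id), float(r.evalue),
                  float(r.coverage), str(r.source))
        for r in df.itertuples()
    ]


def read_go_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a domain -> GO mapping TSV (columns domain_id, go_terms; terms
    comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.domain_id): frozenset(str(r.go_terms).split(","))
        for r in df.itertuples()
        if str(r.go_terms)
    }


def filter_homolog_hits(
    hits: list[AlignmentHit], max_evalue: float = 1e-10
) -> dict[str, list[AlignmentHit]]:
    """Best homolog hit(s) per transcript at the homology e-value cutoff.

    Hits above the (inclusive) threshold are dropped; per transcript the
    minimal-e-value hit is kept, and when several subjects tie at that
    minimal e-value all of them are reported.
    """
    passing: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        if hit.evalue > max_evalue:
            continue
        passing.setdefault(hit.query_id, []).append(hit)
    best: dict[str, list[AlignmentHit]] = {}
    for query, qhits in passing.items():
        min_e = min(h.evalue for h in qhits)
        tied = sorted((h for h in qhits if h.evalue == min_e), key=_rank)
        best[query] = tied
    return best


def filter_domain_hits(
    hits: list[DomainHit], max_evalue: float = 1e-3, min_coverage: float = 0.8
) -> list[DomainHit]:
    """Accept hits with e-value <= max_evalue and coverage >= min_coverage
    (both boundaries inclusive)."""
    return [
        h for h in hits if h.evalue <= max_evalue and h.domain_coverage >= min_coverage
    ]


def transfer_go(
    domain_hits: list[DomainHit], domain_to_go: dict[str, frozenset[str]]
) -> list[GOAssignment]:
    """Per transcript, the union of GO terms of its accepted domains.

    Domains absent from the map contribute nothing; transcripts left with no
    term are omitted, so every assignment is traceable to a source domain.
    """
    terms: dict[str, set[str]] = {}
    sources: dict[str, set[str]] = {}
    order: list[str] = []
    for hit in domain_hits:
        go = domain_to_go.get(hit.domain_id)
        if not go:
            continue
        if hit.transcript_id not in terms:
            terms[hit.transcript_id] = set()
            sources[hit.transcript_id] = set()
            order.append(hit.transcript_id)
        terms[hit.transcript_id] |= go
        sources[hit.transcript_id].add(hit.domain_id)
    return [
        GOAssignment(t, frozenset(terms[t]), frozenset(sources[t])) for t in order
    ]


def domain_frequency(
    domain_hits: list[DomainHit], top_n: int = 20
) -> list[tuple[str, int, float]]:
    """Most frequent domains among accepted hits.

    Returns up to ``top_n`` (domain, count, relative frequency) tuples,
    count-descending with lexicographic tie-break; frequencies are relative
    to all accepted hits.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not domain_hits:
        return []
    counts: dict[str, int] = {}
    for hit in domain_hits:
        counts[hit.domain_id] = counts.get(hit.domain_id, 0) + 1
    total = len(domain_hits)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(d, c, c / total) for d, c in ranked[:top_n]]


def go_enrichment(
    target_transcripts: set[str],
    control_transcripts: set[str],
    assignments: list[GOAssignment],
) -> list[EnrichmentResult]:
    """GO-category enrichment between disjoint target and control sets.

    For every category annotated in either set, a 2x2 chi-square
    (has-category/lacks-category x target/control) without continuity
    correction is computed; a transcript counts once per category. When any
    expected cell is below 5 the p-value comes from Fisher's exact test
    instead (flagged). Raw p-values are Bonferroni-adjusted over the number
    of categories tested and results are sorted by adjusted then raw p.
    """
    if not target_transcripts or not control_transcripts:
        raise ValueError("target and control sets must be non-empty")
    if target_transcripts & control_transcripts:
        raise ValueError("target and control sets must be disjoint")
    by_transcript = {a.transcript_id: a.go_terms for a in assignments}
    categories: set[str] = set()
    for tid in target_transcripts | control_transcripts:
        categories |= by_transcript.get(tid, frozenset())
    n_t = len(target_transcripts)
    n_c = len(control_transcripts)
    n_tests = len(categories)
    results = []
    for cat in sorted(categories):
        k_t = sum(1 for t in target_transcripts if cat in by_transcript.get(t, ()))
        k_c = sum(1 for t in control_transcripts if cat in by_transcript.get(t, ()))
        table = [[k_t, n_t - k_t], [k_c, n_c - k_c]]
        row_t = [k_t + k_c, n_t + n_c - k_t - k_c]
        fisher = False
        if 0 in row_t:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            if expected.min() < 5:
                fisher = True
                p = float(stats.fisher_exact(table).pvalue)
        results.append(
            EnrichmentResult(
                category=cat,
                count_target=k_t,
                count_control=k_c,
                chi2=float(chi2),
                p_raw=float(p),
                p_bonferroni=min(1.0, float(p) * n_tests),
                fisher_fallback=fisher,
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.p_raw, r.category))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    lines = ["category\tcount_target\tcount_control\tchi2\tp_raw\tp_bonferroni\tfisher_fallback"]
    for r in results:
        lines.append(
            f"{r.category}\t{r.count_target}\t{r.count_control}\t{r.chi2:.6g}\t"
            f"{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t{int(r.fisher_fallback)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
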