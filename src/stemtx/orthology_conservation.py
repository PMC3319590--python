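"""Reciprocal-best-hit orthology and cross-species conservation statistics.

Orthologs between the planarian and human gene sets are called by the
reciprocal-best-hit (RBH) criterion on pairwise protein alignment tables:
gene A and gene B are orthologs iff B is A's best hit in the forward search
and A is B's best hit in the reverse search. "Best" means lowest e-value,
ties broken by higher bit score, then lexicographic subject id, which makes
the call deterministic.

Conservation of stem-cell expression is then quantified by cross-tabulating
the per-species enrichment classes over ortholog pairs, and class-pair
proportions are compared with a pooled two-proportion Z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import math

import pandas as pd

__all__ = [
    "AlignmentHit",
    "OrthologPair",
    "ConservationTable",
    "read_hit_table",
    "best_hits",
    "reciprocal_best_hits",
    "collapse_to_genes",
    "conserved_enrichment",
    "two_proportion_ztest",
]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    forward_hit: AlignmentHit
    reverse_hit: AlignmentHit


@dataclass
class ConservationTable:
    """Class-by-class cross-tabulation over ortholog pairs.

    ``counts[(class_a, class_b)]`` counts pairs with both genes classified;
    ``denominators[class_a]`` counts classified pairs whose species-A gene is
    in that class. Pairs with either gene unclassified are tallied in
    ``unclassified_pairs``.
    """

    counts: dict[tuple[str, str], int]
    denominators: dict[str, int]
    unclassified_pairs: int

    @property
    def conserved_stem(self) -> int:
        return self.counts.get(("X1", "hESC_enriched"), 0)

    @property
    def conserved_diff(self) -> int:
        return self.counts.get(("Xins", "hEB_enriched"), 0)

    def to_dict(self) -> dict:
        return {
            "counts": {f"{a}|{b}": n for (a, b), n in sorted(self.counts.items())},
            "denominators": dict(sorted(self.denominators.items())),
            "unclassified_pairs": self.unclassified_pairs,
            "conserved_stem": self.conserved_stem,
            "conserved_diff": self.conserved_diff,
        }


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column tabular alignment file (standard outfmt-6 layout).

    Only query id, subject id, e-value and bit score (columns 1, 2, 11, 12)
    are consumed.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >=12 columns, got {df.shape[1]}")
    return [
        AlignmentHit(str(q), str(s), float(e), float(b))
        for q, s, e, b in zip(df[0], df[1], df[10], df[11])
    ]


def best_hits(
    hits: list[AlignmentHit], max_evalue: float = 1e-10
) -> dict[str, AlignmentHit]:
    """Best subject per query after an e-value cutoff (inclusive <=).

    Ranking: lowest e-value, then highest bit score, then lexicographically
    smallest subject id. Queries with no passing hit are absent.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.evalue > max_evalue:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _rank(hit) < _rank(cur):
            best[hit.query_id] = hit
    return best


def _rank(hit: AlignmentHit) -> tuple:
    return (hit.evalue, -hit.bitscore, hit.subject_id)


def collapse_to_genes(
    hits: list[AlignmentHit],
    query_gene: dict[str, str] | None = None,
    subject_gene: dict[str, str] | None = None,
) -> list[AlignmentHit]:
    """Map transcript-level hits to gene-level hits.

    Transcript ids are replaced by their gene ids (identity when a map is
    None or lacks the id); downstream :func:`best_hits` then keeps each
    gene's single best hit.
    """
    out = []
    for h in hits:
        q = (query_gene or {}).get(h.query_id, h.query_id)
        s = (subject_gene or {}).get(h.subject_id, h.subject_id)
        out.append(AlignmentHit(q, s, h.evalue, h.bitscore))
    return out


def reciprocal_best_hits(
    forward: dict[str, AlignmentHit], reverse: dict[str, AlignmentHit]
) -> list[OrthologPair]:
    """Ortholog pairs (a, b) with forward[a] = b and reverse[b] = a.

    The result is a matching: each gene occurs in at most one pair.
    Pairs are returned sorted by the species-A gene id.
    """
    pairs = []
    for a, fwd in forward.items():
        b = fwd.subject_id
        rev = reverse.get(b)
        if rev is not None and rev.subject_id == a:
            pairs.append(OrthologPair(a, b, fwd, rev))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def conserved_enrichment(
    pairs: list[OrthologPair],
    class_a: dict[str, str],
    class_b: dict[str, str],
) -> ConservationTable:
    """Cross-tabulate species-A vs species-B enrichment classes over pairs.

    Only pairs with both genes classified enter the table; denominators are
    per species-A class.
    """
    counts: dict[tuple[str, str], int] = {}
    denominators: dict[str, int] = {}
    unclassified = 0
    for pair in pairs:
        ca = class_a.get(pair.gene_a)
        cb = class_b.get(pair.gene_b)
        if ca is None or cb is None:
            unclassified += 1
            continue
        counts[(ca, cb)] = counts.get((ca, cb), 0) + 1
        denominators[ca] = denominators.get(ca, 0) + 1
    return ConservationTable(counts, denominators, unclassified)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Pooled two-proportion Z test (two-sided).

    z = (k2/n2 - k1/n1) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    proportion p = (k1+k2)/(n1+n2). When the pooled proportion is degenerate
    (0 or 1) both samples are identical in outcome and p-value 1 is returned
    with a flag.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return {"z": 0.0, "p_two_sided": 1.0, "degenerate": True}
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k2 / n2 - k1 / n1) / se
    # two-sided normal p via erfc for precision in the tails
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return {"z": z, "p_two_sided": p, "degenerate": False}


def write_pairs_tsv(pairs: list[OrthologPair], path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tforward_evalue\tforward_bitscore\treverse_evalue\treverse_bitscore"]
    for p in pairs:
        lines.append(
            f"{p.gene_a}\t{p.gene_b}\t{p.forward_hit.evalue:.3g}\t"
            f"{p.forward_hit.bitscore:.1f}\t{p.reverse_hit.evalue:.3g}\t"
            f"{p.reverse_hit.bitscore:.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
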