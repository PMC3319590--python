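"""Independent reference implementations used only as test oracles.

Each function here re-derives a quantity by exhaustive enumeration,
per-base counting, or permutation, deliberately avoiding the package's own
code paths so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from stemtx.transcript_models import Gene, TranscriptomeAnnotation


def _blocks(tx) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.exons]


def _junctions(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]


def _bases(blocks: list[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in blocks:
        out.update(range(s, e))
    return out


def brute_force_events(gene: Gene) -> set[tuple]:
    """Exhaustive event enumeration straight from the definitions.

    Returns a set of (kind, core-coordinates) tuples; the production
    detector must produce exactly this set (deduplicated). Works by testing
    every exon / intron / junction combination across every isoform pair,
    using per-base membership for the splice-site-extension condition.
    Intended for small genes only.
    """
    if len(gene.transcripts) < 2:
        return set()
    txs = gene.transcripts
    plus = gene.strand != "-"
    found: set[tuple] = set()

    # cassette: internal exon of A skipped by a single junction of B
    for a in txs:
        ba = _blocks(a)
        for i in range(1, len(ba) - 1):
            donor, acceptor = ba[i - 1][1], ba[i + 1][0]
            for b in txs:
                if b is a:
                    continue
                if (donor, acceptor) in _junctions(_blocks(b)):
                    found.add(("cassette", (ba[i],)))

    # retained intron: junction of A inside one exon of B matching the
    # outer boundaries of A's flanking exons
    for a in txs:
        ba = _blocks(a)
        for i, (s, e) in enumerate(_junctions(ba)):
            outer = (ba[i][0], ba[i + 1][1])
            for b in txs:
                if b is a:
                    continue
                if outer in _blocks(b):
                    found.add(("retained_intron", ((s, e),)))

    # alternative 5'/3' splice sites: intron pairs sharing one boundary,
    # with the between-boundaries segment exonic in the long-exon isoform
    for a, b in combinations(txs, 2):
        for ja in _junctions(_blocks(a)):
            for jb in _junctions(_blocks(b)):
                if ja == jb:
                    continue
                if ja[1] == jb[1] and ja[0] != jb[0]:
                    lo, hi = sorted((ja[0], jb[0]))
                    long_tx = a if ja[0] == hi else b
                    if set(range(lo, hi)) <= _bases(_blocks(long_tx)):
                        kind = "alt5ss" if plus else "alt3ss"
                        found.add((kind, ((lo, hi),)))
                elif ja[0] == jb[0] and ja[1] != jb[1]:
                    lo, hi = sorted((ja[1], jb[1]))
                    long_tx = a if ja[1] == lo else b
                    if set(range(lo, hi)) <= _bases(_blocks(long_tx)):
                        kind = "alt3ss" if plus else "alt5ss"
                        found.add((kind, ((lo, hi),)))

    # mutually exclusive exons: internal exon pairs between identical
    # flanks such that every flank-spanning isoform has exactly one
    internal: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for t in txs:
        bt = _blocks(t)
        for i in range(1, len(bt) - 1):
            internal.add(((bt[i - 1][1], bt[i + 1][0]), bt[i]))
    for (fl1, e1), (fl2, e2) in combinations(sorted(internal), 2):
        if fl1 != fl2 or e1 == e2:
            continue
        lo_e, hi_e = sorted((e1, e2))
        if lo_e[1] > hi_e[0]:  # overlap
            continue
        donor, acceptor = fl1
        ok = True
        any_with_first = any_with_second = False
        for t in txs:
            bt = _blocks(t)
            spans = donor in {e for _, e in bt} and acceptor in {s for s, _ in bt}
            if not spans:
                continue
            has1, has2 = lo_e in bt, hi_e in bt
            if has1 and has2 or (not has1 and not has2):
                ok = False
                break
            any_with_first |= has1
            any_with_second |= has2
        if ok and any_with_first and any_with_second:
            found.add(("mutually_exclusive", (lo_e, hi_e)))
    return found


def events_as_set(events) -> set[tuple]:
    return {(ev.kind, tuple(sorted(ev.core))) for ev in events}


def footprints_by_base_count(
    annotation: TranscriptomeAnnotation,
) -> tuple[int, int]:
    """(transcribed, exonic) footprints by per-base occupancy sets."""
    transcribed: dict[str, set[int]] = {}
    exonic: dict[str, set[int]] = {}
    for gene in annotation:
        span = gene.span
        transcribed.setdefault(gene.contig, set()).update(range(span.start, span.end))
        for tx in gene.transcripts:
            for e in tx.exons:
                exonic.setdefault(gene.contig, set()).update(range(e.start, e.end))
    return (
        sum(len(v) for v in transcribed.values()),
        sum(len(v) for v in exonic.values()),
    )


def permutation_two_sample_pvalue(
    a: np.ndarray, b: np.ndarray, n_perm: int, seed: int, statistic
) -> float:
    """Two-sided permutation p-value for any two-sample statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(statistic(a, b))
    count = 0
    n_a = len(a)
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(statistic(pooled[:n_a], pooled[n_a:])) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def exhaustive_mannwhitney_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by complete enumeration of group labelings.

    Valid for tie-free data and small samples only.
    """
    from itertools import combinations as combos

    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(idx_a: tuple[int, ...]) -> float:
        xa = pooled[list(idx_a)]
        xb = np.delete(pooled, list(idx_a))
        return float((xa[:, None] > xb[None, :]).sum())

    observed = u_stat(tuple(range(n_a)))
    n_b = len(pooled) - n_a
    mean_u = n_a * n_b / 2.0
    dev = abs(observed - mean_u)
    total = extreme = 0
    for idx in combos(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total
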