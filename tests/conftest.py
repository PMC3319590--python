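from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from stemtx.synthetic_data import SynthConfig
from stemtx.transcript_models import (
    Exon,
    Gene,
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
)


def make_gene(
    isoform_blocks: list[list[tuple[int, int]]],
    strand: str = "+",
    contig: str = "chr1",
    gene_id: str = "gX",
) -> Gene:
    """Build a gene from lists of (start, end) exon blocks per isoform."""
    txs = []
    for i, blocks in enumerate(isoform_blocks, start=1):
        tid = f"{gene_id}.t{i}"
        exons = [Exon(GenomicInterval(contig, s, e, strand), tid) for s, e in blocks]
        txs.append(Transcript(tid, gene_id, exons))
    return Gene(gene_id, txs)


def make_annotation(genes: list[Gene]) -> TranscriptomeAnnotation:
    ann = TranscriptomeAnnotation()
    for g in genes:
        ann.genes[g.gene_id] = g
    return ann


def random_gene(rng: np.random.Generator, gene_id: str = "gR") -> Gene:
    """A random multi-isoform gene built by perturbing a master exon chain.

    Isoforms drop exons, merge across introns, and jitter boundaries, so
    every event class (and many near-miss structures) arises with useful
    frequency. Coordinates stay small so per-base oracles are cheap.
    """
    n_exons = int(rng.integers(3, 9))
    bounds = np.sort(rng.choice(np.arange(1, 400), size=2 * n_exons, replace=False))
    master = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
    n_iso = int(rng.integers(2, 7))
    isoforms = []
    for _ in range(n_iso):
        for _attempt in range(20):
            blocks = [b for b in master if rng.random() < 0.8]
            if len(blocks) < 1:
                continue
            # merge a random adjacent pair (intron retention structure)
            if len(blocks) >= 2 and rng.random() < 0.3:
                i = int(rng.integers(0, len(blocks) - 1))
                blocks = (
                    blocks[:i] + [(blocks[i][0], blocks[i + 1][1])] + blocks[i + 2 :]
                )
            # jitter one boundary (alternative splice-site structure)
            if rng.random() < 0.4:
                i = int(rng.integers(0, len(blocks)))
                s, e = blocks[i]
                if rng.random() < 0.5:
                    s = s + int(rng.integers(-5, 6))
                else:
                    e = e + int(rng.integers(-5, 6))
                if s < e and s >= 0:
                    blocks[i] = (s, e)
            ok = all(
                blocks[j][1] < blocks[j + 1][0] for j in range(len(blocks) - 1)
            ) and all(s < e for s, e in blocks)
            if ok:
                isoforms.append(blocks)
                break
        else:
            isoforms.append(master)
    strand = "+" if rng.random() < 0.5 else "-"
    return make_gene(isoforms, strand=strand, gene_id=gene_id)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Down-scaled study conditions for fast unit tests."""
    return SynthConfig(
        seed=7,
        n_cassette=25,
        n_retained_intron=15,
        n_mutually_exclusive=6,
        n_alt5ss=10,
        n_alt3ss=9,
        n_filler_genes=40,
        n_transcripts_expression=2500,
        n_ortholog_pairs=120,
        n_decoy_hits=300,
        x1_pairs=35,
        x1_conserved=12,
        x2_pairs=25,
        xins_pairs=30,
        xins_conserved=9,
        n_target_transcripts=150,
        n_control_transcripts=150,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    from stemtx.synthetic_data import generate_annotation

    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config):
    from stemtx.synthetic_data import generate_expression

    return generate_expression(small_config)
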