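"""Synthetic inputs with planted, machine-readable ground truth.

Every pipeline stage is exercised on data this module generates: transcript
models carrying known counts of each alternative-splicing event class, FPKM
matrices with planted strain-bias / irradiation / cell-population /
stemness labels, alignment-hit tables with planted reciprocal-best-hit
pairs plus asymmetric decoys, and domain/GO tables with planted enrichment.

Entities are constructed strictly inside their category regions (a safety
margin keeps values away from thresholds), so rule-based classifiers must
recover every planted label exactly; any miss is a pipeline bug, not
sampling noise. Distributional knobs (length distributions, category
fractions, planted counts) default to the magnitudes of the study the
package models; see docs/methods.md.

A single integer seed drives all generators; each draws from its own
numpy ``default_rng([seed, stream])`` substream, so outputs are
deterministic given the seed and independent across generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_enrichment import DomainHit
from .expression_profiles import ExpressionMatrix, SampleMeta
from .orthology_conservation import AlignmentHit
from .transcript_models import (
    Exon,
    Gene,
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
)

__all__ = [
    "SynthConfig",
    "generate_annotation",
    "generate_expression",
    "generate_orthology",
    "generate_domains",
    "generate_correlated_fpkm",
    "sample_fpkm_mixture",
    "write_bundle",
]

# substream ids for seed splitting
_STREAM_ANNOTATION = 1
_STREAM_EXPRESSION = 2
_STREAM_ORTHOLOGY = 3
_STREAM_DOMAINS = 4
_STREAM_FPKM = 5


@dataclass
class SynthConfig:
    """Knobs for all synthetic generators; defaults are the study conditions."""

    seed: int = 0

    # --- annotation ---
    n_cassette: int = 512
    n_retained_intron: int = 286
    n_mutually_exclusive: int = 36
    n_alt5ss: int = 113
    n_alt3ss: int = 88
    n_filler_genes: int = 1000
    exon_meanlog: float = 5.286  # mean exon length ~272 bp
    exon_sdlog: float = 0.8
    intron_meanlog: float = 7.389  # mean intron length ~2668 bp
    intron_sdlog: float = 1.0
    min_exon_len: int = 9
    min_intron_len: int = 30
    p_frame_cassette: float = 0.73
    p_frame_constitutive: float = 0.35
    p_frame_retained: float = 0.39
    genes_per_contig: int = 50

    # --- expression ---
    n_transcripts_expression: int = 17084
    presence: float = 1.0
    bias_fold: float = 1.25
    hesc_fold: float = 1.3
    frac_unbiased: float = 0.89
    frac_specific: float = 0.06
    frac_biased: float = 0.05
    frac_sexual_side: float = 0.92  # sexual share of specific/biased rows
    frac_irradiation_sensitive: float = 0.28
    # X1/X2/Xins Venn-region weights (counts; remainder of rows expressed nowhere)
    venn_weights: dict = field(
        default_factory=lambda: {
            "X1": 252,
            "X2": 368,
            "Xins": 878,
            "X1_X2": 154,
            "X1_Xins": 341,
            "X2_Xins": 1872,
            "X1_X2_Xins": 10657,
        }
    )
    frac_hesc_enriched: float = 0.29
    frac_heb_enriched: float = 0.39
    margin: float = 1e-3  # relative safety margin away from thresholds

    # --- orthology ---
    n_ortholog_pairs: int = 1729
    n_decoy_hits: int = 5000
    x1_pairs: int = 455
    x1_conserved: int = 95
    x2_pairs: int = 432
    xins_pairs: int = 397
    xins_conserved: int = 123
    homolog_max_evalue: float = 1e-10

    # --- domains / GO ---
    n_target_transcripts: int = 500
    n_control_transcripts: int = 500
    enriched_freq_target: float = 0.4
    enriched_freq_control: float = 0.05
    n_background_categories: int = 10
    background_freq: float = 0.1
    n_boundary_hits: int = 5
    domain_max_evalue: float = 1e-3
    domain_min_coverage: float = 0.8

    def validate(self) -> None:
        fracs = (self.frac_unbiased, self.frac_specific, self.frac_biased)
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("bias fractions must sum to 1")
        for name in (
            "frac_sexual_side",
            "frac_irradiation_sensitive",
            "frac_hesc_enriched",
            "frac_heb_enriched",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.frac_hesc_enriched + self.frac_heb_enriched > 1.0:
            raise ValueError("hESC + hEB fractions exceed 1")
        if sum(self.venn_weights.values()) <= 0:
            raise ValueError("Venn weights must have positive mass")
        if self.x1_conserved > self.x1_pairs or self.xins_conserved > self.xins_pairs:
            raise ValueError("conserved counts cannot exceed class pair counts")
        if self.x1_pairs + self.x2_pairs + self.xins_pairs > self.n_ortholog_pairs:
            raise ValueError("classified pairs exceed total ortholog pairs")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _apportion(total: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` items over weights."""
    mass = sum(weights.values())
    raw = {k: total * w / mass for k, w in weights.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(weights, key=lambda k: (counts[k] + 1 - raw[k], k))[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------

def _frame_length(
    rng: np.random.Generator,
    meanlog: float,
    sdlog: float,
    in_frame: bool,
    minimum: int,
) -> int:
    length = max(int(rng.lognormal(meanlog, sdlog)), minimum, 4)
    rem = length % 3
    if in_frame:
        length -= rem
        if length < max(minimum, 3):
            length += 3
    elif rem == 0:
        length += int(rng.integers(1, 3))
    return length


class _Layout:
    """Sequential placement of genes along contigs."""

    def __init__(self, rng: np.random.Generator, genes_per_contig: int):
        self.rng = rng
        self.genes_per_contig = genes_per_contig
        self.gene_index = 0
        self.cursor = 0

    def next_gene(self) -> tuple[str, int]:
        contig = f"scaffold_{self.gene_index // self.genes_per_contig:05d}"
        if self.gene_index % self.genes_per_contig == 0:
            self.cursor = 0
        start = self.cursor + int(self.rng.integers(500, 2000))
        self.gene_index += 1
        return contig, start


def _make_transcripts(
    gene_id: str, contig: str, strand: str, isoform_blocks: list[list[tuple[int, int]]]
) -> Gene:
    txs = []
    for t, blocks in enumerate(isoform_blocks, start=1):
        tid = f"{gene_id}.t{t}"
        exons = [Exon(GenomicInterval(contig, s, e, strand), tid) for s, e in blocks]
        txs.append(Transcript(tid, gene_id, exons))
    return Gene(gene_id, txs)


def generate_annotation(
    config: SynthConfig,
) -> tuple[TranscriptomeAnnotation, dict[str, pd.DataFrame]]:
    """Transcript models with planted alternative-splicing events.

    One planted event per event gene, realized by exactly the isoform pair
    (or triple structure, for mutually exclusive exons) that the event
    definition requires and nothing else between its flanks; single-isoform
    filler genes contribute constitutive internal exons.

    Returns the annotation plus a truth dictionary with two frames:
    ``events`` (gene, kind, core coordinates, strand) and ``exon_classes``
    (planted cassette/constitutive exon lengths with their frame class).
    """
    config.validate()
    rng = _rng(config, _STREAM_ANNOTATION)
    layout = _Layout(rng, config.genes_per_contig)
    annotation = TranscriptomeAnnotation()
    event_rows = []
    exon_rows = []
    gene_no = 0

    def new_gene_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"g{gene_no:06d}"

    def exon_len() -> int:
        return max(int(rng.lognormal(config.exon_meanlog, config.exon_sdlog)),
                   config.min_exon_len)

    def intron_len() -> int:
        return max(int(rng.lognormal(config.intron_meanlog, config.intron_sdlog)),
                   config.min_intron_len)

    plan = (
        [("cassette", None)] * config.n_cassette
        + [("retained_intron", None)] * config.n_retained_intron
        + [("mutually_exclusive", None)] * config.n_mutually_exclusive
        + [("alt5ss", None)] * config.n_alt5ss
        + [("alt3ss", None)] * config.n_alt3ss
    )
    for kind, _ in plan:
        gid = new_gene_id()
        contig, a = layout.next_gene()
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "cassette":
            in_frame = bool(rng.random() < config.p_frame_cassette)
            f1, f2 = exon_len(), exon_len()
            core = _frame_length(
                rng, config.exon_meanlog, config.exon_sdlog, in_frame,
                config.min_exon_len,
            )
            i1, i2 = intron_len(), intron_len()
            b = a + f1
            c = b + i1
            d = c + core
            e = d + i2
            f = e + f2
            iso1 = [(a, b), (c, d), (e, f)]
            iso2 = [(a, b), (e, f)]
            gene = _make_transcripts(gid, contig, strand, [iso1, iso2])
            event_rows.append((gid, kind, contig, c, d, -1, -1, strand))
            exon_rows.append((gid, "cassette", c, d, core, core % 3 == 0))
            end = f
        elif kind == "retained_intron":
            in_frame = bool(rng.random() < config.p_frame_retained)
            f1, f2 = exon_len(), exon_len()
            core = _frame_length(
                rng, config.intron_meanlog, config.intron_sdlog, in_frame,
                config.min_intron_len,
            )
            b = a + f1
            c = b + core
            d = c + f2
            iso1 = [(a, b), (c, d)]
            iso2 = [(a, d)]
            gene = _make_transcripts(gid, contig, strand, [iso1, iso2])
            event_rows.append((gid, kind, contig, b, c, -1, -1, strand))
            end = d
        elif kind == "mutually_exclusive":
            f1, e1_len, e2_len, f2 = exon_len(), exon_len(), exon_len(), exon_len()
            i1, i2, i3 = intron_len(), intron_len(), intron_len()
            b = a + f1
            c = b + i1
            d = c + e1_len
            e = d + i2
            f = e + e2_len
            g = f + i3
            h = g + f2
            iso1 = [(a, b), (c, d), (g, h)]
            iso2 = [(a, b), (e, f), (g, h)]
            gene = _make_transcripts(gid, contig, strand, [iso1, iso2])
            event_rows.append((gid, kind, contig, c, d, e, f, strand))
            end = h
        else:  # alt5ss / alt3ss
            # variable-left-boundary structure yields alt5ss on '+', alt3ss
            # on '-'; variable-right the converse
            variable_left = (kind == "alt5ss") == (strand == "+")
            f1, f2 = exon_len(), exon_len()
            ext = max(int(rng.lognormal(3.5, 0.6)), 6)  # extension segment
            intr = intron_len()
            if variable_left:
                b = a + f1
                bp = b + ext
                c = bp + intr
                d = c + f2
                iso1 = [(a, b), (c, d)]
                iso2 = [(a, bp), (c, d)]
                core_start, core_end = b, bp
                end = d
            else:
                b = a + f1
                c = b + intr
                cp = c + ext
                d = cp + f2
                iso1 = [(a, b), (c, d)]
                iso2 = [(a, b), (cp, d)]
                core_start, core_end = c, cp
                end = d
            gene = _make_transcripts(gid, contig, strand, [iso1, iso2])
            event_rows.append((gid, kind, contig, core_start, core_end, -1, -1, strand))
        annotation.genes[gid] = gene
        layout.cursor = end

    # filler genes: single isoform, internal exons are constitutive
    for _ in range(config.n_filler_genes):
        gid = new_gene_id()
        contig, a = layout.next_gene()
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 7))
        blocks = []
        pos = a
        for i in range(n_exons):
            internal = 0 < i < n_exons - 1
            if internal:
                in_frame = bool(rng.random() < config.p_frame_constitutive)
                length = _frame_length(
                    rng, config.exon_meanlog, config.exon_sdlog, in_frame,
                    config.min_exon_len,
                )
            else:
                length = exon_len()
            blocks.append((pos, pos + length))
            if internal:
                exon_rows.append(
                    (gid, "constitutive", pos, pos + length, length, length % 3 == 0)
                )
            pos += length + intron_len()
        gene = _make_transcripts(gid, contig, strand, [blocks])
        annotation.genes[gid] = gene
        layout.cursor = blocks[-1][1]

    truth = {
        "events": pd.DataFrame(
            event_rows,
            columns=["gene_id", "kind", "contig", "start", "end", "start2", "end2", "strand"],
        ),
        "exon_classes": pd.DataFrame(
            exon_rows,
            columns=["gene_id", "exon_class", "start", "end", "length", "in_frame"],
        ),
    }
    return annotation, truth


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

_SAMPLES = [
    SampleMeta("sexual_NIR", "sexual", "NIR", "whole"),
    SampleMeta("sexual_IR", "sexual", "IR", "whole"),
    SampleMeta("asexual_NIR", "asexual", "NIR", "whole"),
    SampleMeta("asexual_IR", "asexual", "IR", "whole"),
    SampleMeta("X1", "sexual", "none", "X1"),
    SampleMeta("X2", "sexual", "none", "X2"),
    SampleMeta("Xins", "sexual", "none", "Xins"),
    SampleMeta("hESC", "human", "none", "hESC"),
    SampleMeta("hEB", "human", "none", "hEB"),
]


def _expressed_value(rng: np.random.Generator, presence: float, size=None):
    """Clearly-expressed FPKM: presence floor plus a heavy-tailed excess."""
    return presence * 1.1 + rng.lognormal(1.5, 1.0, size=size)


def generate_expression(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """FPKM matrix over the full sample design with planted labels.

    Rows are assigned to strain-bias categories, irradiation sensitivity,
    an X1/X2/Xins Venn region with a designated argmax population, and an
    hESC/hEB class, each by deterministic apportionment of the configured
    fractions; values are then drawn strictly inside the corresponding
    category region. The returned truth frame has one row per transcript
    with every planted label.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)
    n = config.n_transcripts_expression
    presence = config.presence
    lo_margin = presence * (1.0 - 10 * config.margin)

    ids = [f"t{i:06d}" for i in range(n)]

    # ---- strain bias ----
    counts = _apportion(
        n,
        {
            "unbiased": config.frac_unbiased,
            "specific": config.frac_specific,
            "biased": config.frac_biased,
        },
    )
    sex_specific = _apportion(
        counts["specific"], {"sexual": config.frac_sexual_side,
                            "asexual": 1 - config.frac_sexual_side}
    )
    sex_biased = _apportion(
        counts["biased"], {"sexual": config.frac_sexual_side,
                           "asexual": 1 - config.frac_sexual_side}
    )
    categories = (
        ["unbiased"] * counts["unbiased"]
        + ["sexual_specific"] * sex_specific["sexual"]
        + ["asexual_specific"] * sex_specific["asexual"]
        + ["sexual_biased"] * sex_biased["sexual"]
        + ["asexual_biased"] * sex_biased["asexual"]
    )
    categories = [categories[i] for i in rng.permutation(n)]

    sex_nir = np.empty(n)
    asex_nir = np.empty(n)
    fold = config.bias_fold
    for i, cat in enumerate(categories):
        base = _expressed_value(rng, presence)
        if cat == "unbiased":
            ratio = rng.uniform(1.0, fold * (1 - 10 * config.margin))
            hi, lo = base * ratio, base
            if rng.random() < 0.5:
                sex_nir[i], asex_nir[i] = hi, lo
            else:
                sex_nir[i], asex_nir[i] = lo, hi
        elif cat.endswith("_biased"):
            ratio = rng.uniform(fold * (1 + config.margin), fold * 4)
            if cat == "sexual_biased":
                sex_nir[i], asex_nir[i] = base * ratio, base
            else:
                sex_nir[i], asex_nir[i] = base, base * ratio
        else:  # specific
            off = rng.uniform(0.0, lo_margin)
            if cat == "sexual_specific":
                sex_nir[i], asex_nir[i] = base, off
            else:
                sex_nir[i], asex_nir[i] = off, base

    # ---- irradiation ----
    n_sens = _apportion(n, {"sensitive": config.frac_irradiation_sensitive,
                            "insensitive": 1 - config.frac_irradiation_sensitive})
    irr = np.array(
        ["sensitive"] * n_sens["sensitive"] + ["insensitive"] * n_sens["insensitive"]
    )[rng.permutation(n)]
    sens_mask = irr == "sensitive"
    down = rng.uniform(0.3, 0.9, size=(n, 2))
    up = rng.uniform(1.0, 1.5, size=(n, 2))
    factor = np.where(sens_mask[:, None], down, up)
    sex_ir = sex_nir * factor[:, 0]
    asex_ir = asex_nir * factor[:, 1]

    # ---- X1/X2/Xins Venn regions and argmax population ----
    weights = dict(config.venn_weights)
    total_w = sum(weights.values())
    if total_w > n:
        region_counts = _apportion(n, weights)
    else:
        region_counts = {k: int(v) for k, v in weights.items()}
        region_counts["none"] = n - sum(region_counts.values())
    region_list: list[str] = []
    for region, cnt in region_counts.items():
        region_list += [region] * cnt
    regions = np.array(region_list)[rng.permutation(n)]

    pops = ("X1", "X2", "Xins")
    pop_values = np.empty((n, 3))
    argmax_pop = np.empty(n, dtype=object)
    for i, region in enumerate(regions):
        members = [] if region == "none" else region.split("_")
        vals = {}
        for p in pops:
            if p in members:
                vals[p] = _expressed_value(rng, presence)
            else:
                vals[p] = rng.uniform(0.0, lo_margin)
        if members:
            # designate a strict argmax among the expressed populations
            top = str(rng.choice(members))
            ceiling = max(vals.values())
            vals[top] = ceiling * rng.uniform(1.3, 3.0) + 10 * config.margin
        else:
            # expressed nowhere: keep everything under the presence floor
            # but still strictly ordered so the argmax is well defined
            draws = np.sort(rng.uniform(0.0, lo_margin, size=3))
            top = str(rng.choice(list(pops)))
            others = [p for p in pops if p != top]
            vals[top] = float(draws[2])
            vals[others[0]] = float(draws[0])
            vals[others[1]] = float(draws[1])
        argmax_pop[i] = top
        pop_values[i] = [vals[p] for p in pops]

    # ---- hESC / hEB ----
    h_counts = _apportion(
        n,
        {
            "hESC_enriched": config.frac_hesc_enriched,
            "hEB_enriched": config.frac_heb_enriched,
            "neither": 1 - config.frac_hesc_enriched - config.frac_heb_enriched,
        },
    )
    h_cat = np.array(
        ["hESC_enriched"] * h_counts["hESC_enriched"]
        + ["hEB_enriched"] * h_counts["hEB_enriched"]
        + ["neither"] * h_counts["neither"]
    )[rng.permutation(n)]
    hfold = config.hesc_fold
    hesc = np.empty(n)
    heb = np.empty(n)
    for i, cat in enumerate(h_cat):
        base = rng.lognormal(1.0, 1.0) + 0.05
        if cat == "hESC_enriched":
            heb[i] = base
            hesc[i] = base * rng.uniform(hfold * (1 + config.margin), hfold * 3)
        elif cat == "hEB_enriched":
            hesc[i] = base
            heb[i] = base * rng.uniform(hfold * (1 + config.margin), hfold * 3)
        else:
            hesc[i] = base
            heb[i] = base * rng.uniform(
                (1.0 / hfold) * (1 + 10 * config.margin),
                hfold * (1 - 10 * config.margin),
            )

    values = pd.DataFrame(
        {
            "sexual_NIR": sex_nir,
            "sexual_IR": sex_ir,
            "asexual_NIR": asex_nir,
            "asexual_IR": asex_ir,
            "X1": pop_values[:, 0],
            "X2": pop_values[:, 1],
            "Xins": pop_values[:, 2],
            "hESC": hesc,
            "hEB": heb,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    matrix = ExpressionMatrix(values, list(_SAMPLES))

    expressed_in = [
        "" if r == "none" else ",".join(sorted(r.split("_"))) for r in regions
    ]
    specific_to = [
        r if r in pops else "" for r in regions
    ]
    truth = pd.DataFrame(
        {
            "bias_category": categories,
            "irradiation": irr,
            "venn_region": regions,
            "enriched_in": argmax_pop,
            "specific_to": specific_to,
            "expressed_in": expressed_in,
            "hesc_category": h_cat,
        },
        index=values.index,
    )
    return matrix, truth


def sample_fpkm_mixture(
    n: int, seed: int = 0, frac_below: float = 0.92, threshold: float = 1.0
) -> np.ndarray:
    """Whole-transcriptome FPKM mixture: a configured mass at or below the
    presence threshold (weak/absent transcripts) plus a log-normal tail
    above it. Mirrors an expression distribution whose presence cutoff sits
    at a high percentile."""
    rng = np.random.default_rng([seed, _STREAM_FPKM])
    below = rng.uniform(0.0, threshold, size=n)
    above = threshold + rng.lognormal(1.0, 1.5, size=n)
    take_below = rng.random(n) < frac_below
    return np.where(take_below, below, above)


def generate_correlated_fpkm(
    n: int, target_r: float = 0.92, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate FPKM columns whose log2(1+FPKM) correlation targets ``target_r``.

    Draws correlated bivariate normals in log2 space and maps them back
    through FPKM = 2^z - 1 (clipped at 0; the clip touches a negligible
    tail mass).
    """
    rng = np.random.default_rng([seed, _STREAM_FPKM])
    mu, sd = 4.0, 1.5
    z1 = rng.normal(size=n)
    z2 = target_r * z1 + math.sqrt(1 - target_r**2) * rng.normal(size=n)
    x = np.maximum(2.0 ** (mu + sd * z1) - 1.0, 0.0)
    y = np.maximum(2.0 ** (mu + sd * z2) - 1.0, 0.0)
    return x, y


# ---------------------------------------------------------------------------
# Orthology generator
# ---------------------------------------------------------------------------

def generate_orthology(config: SynthConfig) -> dict:
    """Hit tables with planted reciprocal-best-hit pairs and decoys.

    Planted pairs are mutually best (their reciprocal hits dominate every
    competing hit for both genes); decoys are one-directional or dominated
    hits that RBH must reject. Per-species enrichment class maps realize the
    configured conservation structure (e.g. 95 of 455 X1 orthologs
    conserved in hESCs, 123 of 397 Xins orthologs conserved in hEBs).

    Returns a dict with ``forward_hits``, ``reverse_hits`` (AlignmentHit
    lists), ``class_a``, ``class_b`` (gene -> class maps) and ``truth``
    (DataFrame of planted pairs with their class assignments).
    """
    config.validate()
    rng = _rng(config, _STREAM_ORTHOLOGY)
    npairs = config.n_ortholog_pairs
    a_genes = [f"smed_g{i:05d}" for i in range(npairs)]
    b_genes = [f"hsap_g{i:05d}" for i in range(npairs)]

    forward: list[AlignmentHit] = []
    reverse: list[AlignmentHit] = []
    best_e = 10.0 ** (-rng.uniform(15, 170, size=npairs))
    for i in range(npairs):
        bits = float(rng.uniform(80, 600))
        forward.append(AlignmentHit(a_genes[i], b_genes[i], float(best_e[i]), bits))
        reverse.append(AlignmentHit(b_genes[i], a_genes[i], float(best_e[i]), bits))

    # decoys: extra genes with asymmetric hits, plus dominated competing hits
    n_decoy = config.n_decoy_hits
    for d in range(n_decoy):
        j = int(rng.integers(0, npairs))
        worse_e = min(float(best_e[j]) * 10.0 ** float(rng.uniform(2, 6)), 1e-11)
        bits = float(rng.uniform(40, 200))
        mode = d % 3
        if mode == 0:
            # forward-only decoy query: best hit not reciprocated
            forward.append(AlignmentHit(f"smed_d{d:05d}", b_genes[j], worse_e, bits))
        elif mode == 1:
            reverse.append(AlignmentHit(f"hsap_d{d:05d}", a_genes[j], worse_e, bits))
        else:
            # dominated competing hit between planted genes
            k = int(rng.integers(0, npairs))
            if k != j:
                forward.append(AlignmentHit(a_genes[j], b_genes[k], worse_e, bits))

    # class assignments over a permutation of the planted pairs
    order = rng.permutation(npairs)
    class_a: dict[str, str] = {}
    class_b: dict[str, str] = {}
    rows = []
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = order[cursor : cursor + k]
        cursor += k
        return list(out)

    groups = [
        ("X1", config.x1_pairs, config.x1_conserved, "hESC_enriched"),
        ("X2", config.x2_pairs, 0, None),
        ("Xins", config.xins_pairs, config.xins_conserved, "hEB_enriched"),
    ]
    for cls_a, n_cls, n_cons, cons_b in groups:
        members = take(n_cls)
        for rank, idx in enumerate(members):
            class_a[a_genes[idx]] = cls_a
            if cons_b is not None and rank < n_cons:
                cb = cons_b
            else:
                # non-conserved partners avoid the conserved class
                avoid = cons_b
                options = [
                    c for c in ("hESC_enriched", "hEB_enriched", "neither") if c != avoid
                ]
                cb = str(rng.choice(options))
            class_b[b_genes[idx]] = cb
            rows.append((a_genes[idx], b_genes[idx], cls_a, cb))
    for idx in order[cursor:]:
        # remaining pairs: species-A gene unclassified
        cb = str(rng.choice(["hESC_enriched", "hEB_enriched", "neither"]))
        class_b[b_genes[idx]] = cb
        rows.append((a_genes[idx], b_genes[idx], "", cb))

    truth = pd.DataFrame(rows, columns=["gene_a", "gene_b", "class_a", "class_b"])
    truth = truth.sort_values("gene_a").reset_index(drop=True)
    return {
        "forward_hits": forward,
        "reverse_hits": reverse,
        "class_a": class_a,
        "class_b": class_b,
        "truth": truth,
    }


def write_hit_table(hits: list[AlignmentHit], path: str | Path) -> None:
    """Write hits as 12-column tabular alignment records (outfmt-6 layout)."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.query_id}\t{h.subject_id}\t50.0\t100\t0\t0\t1\t100\t1\t100\t"
            f"{h.evalue:.3e}\t{h.bitscore:.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Domain / GO generator
# ---------------------------------------------------------------------------

def generate_domains(config: SynthConfig) -> dict:
    """Domain-hit and GO-map tables with a planted enriched category.

    The enriched category's carrier domain appears in target transcripts at
    ``enriched_freq_target`` and in controls at ``enriched_freq_control``;
    background categories appear at the same frequency in both sets. A few
    hits sit exactly on the acceptance boundaries (e-value 1e-3, coverage
    0.80) and must survive filtering; an equal number of near-miss hits
    must not. One domain is deliberately absent from the GO map.

    Returns ``hits``, ``go_map``, ``target_ids``, ``control_ids`` and a
    ``truth`` DataFrame of per-transcript accepted domains/terms.
    """
    config.validate()
    rng = _rng(config, _STREAM_DOMAINS)
    target_ids = [f"tgt{i:05d}" for i in range(config.n_target_transcripts)]
    control_ids = [f"ctl{i:05d}" for i in range(config.n_control_transcripts)]

    enriched_domain = "D_ENRICHED"
    enriched_go = "GO:1000001"
    go_map: dict[str, frozenset[str]] = {enriched_domain: frozenset([enriched_go])}
    bg_domains = []
    for k in range(config.n_background_categories):
        dom = f"D_BG{k:03d}"
        go_map[dom] = frozenset([f"GO:20000{k:02d}"])
        bg_domains.append(dom)
    unmapped_domain = "D_UNMAPPED"

    hits: list[DomainHit] = []
    truth_rows = []

    def passing_hit(tid: str, dom: str) -> DomainHit:
        return DomainHit(
            tid,
            dom,
            evalue=float(10.0 ** (-rng.uniform(4, 30))),
            domain_coverage=float(rng.uniform(0.82, 1.0)),
        )

    for tid in target_ids + control_ids:
        in_target = tid.startswith("tgt")
        accepted: set[str] = set()
        p_enriched = (
            config.enriched_freq_target if in_target else config.enriched_freq_control
        )
        if rng.random() < p_enriched:
            hits.append(passing_hit(tid, enriched_domain))
            accepted.add(enriched_domain)
        for dom in bg_domains:
            if rng.random() < config.background_freq:
                hits.append(passing_hit(tid, dom))
                accepted.add(dom)
        # failing decoys: bad e-value or bad coverage
        if rng.random() < 0.3:
            hits.append(
                DomainHit(tid, unmapped_domain,
                          evalue=float(10.0 ** (-rng.uniform(0, 2.5))),
                          domain_coverage=float(rng.uniform(0.82, 1.0)))
            )
        if rng.random() < 0.3:
            hits.append(
                DomainHit(tid, str(rng.choice(bg_domains)),
                          evalue=float(10.0 ** (-rng.uniform(4, 30))),
                          domain_coverage=float(rng.uniform(0.0, 0.79)))
            )
        terms = frozenset().union(*(go_map.get(d, frozenset()) for d in accepted)) \
            if accepted else frozenset()
        truth_rows.append(
            (tid, "target" if in_target else "control",
             ",".join(sorted(accepted)), ",".join(sorted(terms)))
        )

    # exact-boundary hits: must survive the inclusive filters
    boundary_dom = bg_domains[0]
    for k in range(config.n_boundary_hits):
        tid = target_ids[k % len(target_ids)]
        hits.append(DomainHit(tid, boundary_dom,
                              evalue=config.domain_max_evalue,
                              domain_coverage=config.domain_min_coverage))

    truth = pd.DataFrame(
        truth_rows, columns=["transcript_id", "set", "accepted_domains", "go_terms"]
    )
    return {
        "hits": hits,
        "go_map": go_map,
        "target_ids": set(target_ids),
        "control_ids": set(control_ids),
        "enriched_category": enriched_go,
        "truth": truth,
    }


def write_domain_hits(hits: list[DomainHit], path: str | Path) -> None:
    lines = ["transcript_id\tdomain_id\tsource\tevalue\tcoverage"]
    for h in hits:
        lines.append(
            f"{h.transcript_id}\t{h.domain_id}\t{h.source}\t{h.evalue:.6e}\t"
            f"{h.domain_coverage:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_go_map(go_map: dict[str, frozenset[str]], path: str | Path) -> None:
    lines = ["domain_id\tgo_terms"]
    for dom in sorted(go_map):
        lines.append(f"{dom}\t{','.join(sorted(go_map[dom]))}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def write_bundle(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input and write it under ``out_dir``.

    Produces the GTF, expression matrix + sample metadata, orthology hit
    tables + class maps, domain/GO tables, and one truth TSV per generator.
    Returns a name -> path map of everything written.
    """
    from .transcript_models import write_gtf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    annotation, ann_truth = generate_annotation(config)
    paths["gtf"] = out / "annotation.gtf"
    write_gtf(annotation, paths["gtf"])
    for name, frame in ann_truth.items():
        paths[f"truth_{name}"] = out / f"truth_{name}.tsv"
        frame.to_csv(paths[f"truth_{name}"], sep="\t", index=False)

    matrix, expr_truth = generate_expression(config)
    paths["matrix"] = out / "fpkm_matrix.tsv"
    paths["samples"] = out / "samples.tsv"
    matrix.write(paths["matrix"], paths["samples"])
    paths["truth_expression"] = out / "truth_expression.tsv"
    expr_truth.to_csv(paths["truth_expression"], sep="\t")

    orth = generate_orthology(config)
    paths["forward_hits"] = out / "forward_hits.tsv"
    paths["reverse_hits"] = out / "reverse_hits.tsv"
    write_hit_table(orth["forward_hits"], paths["forward_hits"])
    write_hit_table(orth["reverse_hits"], paths["reverse_hits"])
    for side in ("a", "b"):
        p = out / f"class_{side}.tsv"
        paths[f"class_{side}"] = p
        cmap = orth[f"class_{side}"]
        p.write_text(
            "gene_id\tclass\n"
            + "\n".join(f"{g}\t{c}" for g, c in sorted(cmap.items()))
            + "\n"
        )
    paths["truth_orthology"] = out / "truth_orthology.tsv"
    orth["truth"].to_csv(paths["truth_orthology"], sep="\t", index=False)

    dom = generate_domains(config)
    paths["domain_hits"] = out / "domain_hits.tsv"
    write_domain_hits(dom["hits"], paths["domain_hits"])
    paths["go_map"] = out / "go_map.tsv"
    write_go_map(dom["go_map"], paths["go_map"])
    paths["truth_domains"] = out / "truth_domains.tsv"
    dom["truth"].to_csv(paths["truth_domains"], sep="\t", index=False)
    (out / "target_ids.txt").write_text("\n".join(sorted(dom["target_ids"])) + "\n")
    (out / "control_ids.txt").write_text("\n".join(sorted(dom["control_ids"])) + "\n")
    paths["target_ids"] = out / "target_ids.txt"
    paths["control_ids"] = out / "control_ids.txt"
    return paths
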