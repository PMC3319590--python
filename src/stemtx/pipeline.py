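"""End-to-end orchestration: annotation summary -> splicing events ->
expression classification -> orthology/conservation -> GO enrichment.

The pipeline is a pure function of (inputs, configuration): rerunning a
config never changes results. Stages whose inputs are absent are skipped
with a logged notice, so partial bundles (e.g. no human data) still
produce a report. Every output header echoes the thresholds used.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation_enrichment import (
    filter_domain_hits,
    go_enrichment,
    read_domain_hits,
    read_go_map,
    transfer_go,
    write_enrichment_tsv,
)
from .expression_profiles import (
    classify_cell_enrichment_table,
    classify_hesc_table,
    classify_irradiation_table,
    classify_strain_bias_table,
    filter_expressed,
    population_overlap,
    read_expression,
    strain_correlation,
    zscore_rows,
)
from .orthology_conservation import (
    best_hits,
    conserved_enrichment,
    read_hit_table,
    reciprocal_best_hits,
    two_proportion_ztest,
    write_pairs_tsv,
)
from .splicing_events import (
    classify_frame,
    constitutive_exons,
    detect_events_annotation,
    frame_bias_test,
    summarize_events,
    write_events_tsv,
)
from .transcript_models import read_gtf, summarize_annotation, write_gtf

logger = logging.getLogger("stemtx")

__all__ = ["PipelineConfig", "Report", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: Path
    gtf: Path | None = None
    fasta: Path | None = None
    matrix: Path | None = None
    samples: Path | None = None
    forward_hits: Path | None = None
    reverse_hits: Path | None = None
    class_a: Path | None = None
    class_b: Path | None = None
    domain_hits: Path | None = None
    go_map: Path | None = None
    target_ids: Path | None = None
    control_ids: Path | None = None
    min_fpkm: float = 1.0
    bias_fold: float = 1.25
    hesc_fold: float = 1.3
    homolog_evalue: float = 1e-10
    domain_evalue: float = 1e-3
    domain_coverage: float = 0.8

    def __post_init__(self):
        for name in ("min_fpkm", "homolog_evalue", "domain_evalue", "domain_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bias_fold", "hesc_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")

    def thresholds(self) -> dict:
        return {
            "min_fpkm": self.min_fpkm,
            "bias_fold": self.bias_fold,
            "hesc_fold": self.hesc_fold,
            "homolog_evalue": self.homolog_evalue,
            "domain_evalue": self.domain_evalue,
            "domain_coverage": self.domain_coverage,
        }


@dataclass
class Report:
    outputs: dict[str, str] = field(default_factory=dict)
    headline: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "thresholds": self.thresholds,
            "outputs": self.outputs,
            "headline": self.headline,
            "skipped_stages": self.skipped,
        }

    def write(self, out_dir: Path) -> None:
        (out_dir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, default=str) + "\n"
        )
        lines = [f"stemtx pipeline report (version {self.version})", ""]
        lines.append("thresholds: " + ", ".join(f"{k}={v}" for k, v in self.thresholds.items()))
        if self.skipped:
            lines.append("skipped stages: " + ", ".join(self.skipped))
        lines.append("")
        for key, value in self.headline.items():
            lines.append(f"{key}: {value}")
        (out_dir / "report.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> Report:
    """Run every stage whose inputs are present; write outputs + report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(thresholds=config.thresholds())
    annotation = None

    if config.gtf is not None:
        logger.info("[annotation] reading %s", config.gtf)
        annotation = read_gtf(config.gtf)
        summary = summarize_annotation(annotation)
        summary.to_json(out / "annotation_summary.json")
        summary.to_tsv(out / "annotation_summary.tsv")
        report.outputs["annotation_summary"] = str(out / "annotation_summary.json")
        report.headline["gene_count"] = summary.gene_count
        report.headline["transcript_count"] = summary.transcript_count
        report.headline["exon_count"] = summary.exon_count
        report.headline["intron_count"] = summary.intron_count

        logger.info("[splicing] detecting events")
        events = detect_events_annotation(annotation)
        write_events_tsv(events, out / "splice_events.tsv")
        ev_summary = summarize_events(events)
        (out / "splice_event_summary.json").write_text(
            json.dumps(ev_summary.to_dict(), indent=2) + "\n"
        )
        report.outputs["splice_events"] = str(out / "splice_events.tsv")
        report.headline["splice_events"] = ev_summary.to_dict()

        cassette_lengths = [
            iv.length
            for ev in events
            if ev.kind == "cassette"
            for iv in ev.core_intervals
        ]
        constitutive_lengths = [e.length for e in constitutive_exons(annotation)]
        if cassette_lengths and constitutive_lengths:
            bias = frame_bias_test(cassette_lengths, constitutive_lengths)
            report.headline["frame_bias"] = {
                k: bias[k]
                for k in ("chi2", "p", "frame_fraction_cassette", "frame_fraction_constitutive")
            }
    else:
        report.skipped.append("annotation")
        logger.info("[annotation] no GTF provided; skipping")

    if config.fasta is not None:
        from .transcript_models import gc_content

        seqs = _read_fasta(config.fasta)
        report.headline["gc_content"] = gc_content(list(seqs.values()))
    elif config.gtf is not None:
        logger.info("[annotation] no FASTA provided; GC content skipped")

    if config.matrix is not None and config.samples is not None:
        logger.info("[expression] reading %s", config.matrix)
        matrix = read_expression(config.matrix, config.samples)
        expressed = filter_expressed(matrix, min_fpkm=config.min_fpkm)
        report.headline["transcripts_expressed"] = expressed.n_transcripts

        def _have(**criteria) -> bool:
            try:
                matrix.column_for(**criteria)
                return True
            except KeyError:
                return False

        if _have(strain="sexual", irradiation="NIR", population="whole") and _have(
            strain="asexual", irradiation="NIR", population="whole"
        ):
            bias_table = classify_strain_bias_table(
                matrix, fold=config.bias_fold, presence=config.min_fpkm
            )
            bias_table.to_csv(out / "strain_bias.tsv", sep="\t")
            report.outputs["strain_bias"] = str(out / "strain_bias.tsv")
            report.headline["strain_bias_counts"] = (
                bias_table["category"].value_counts().to_dict()
            )
            report.headline["strain_correlation_r"] = strain_correlation(matrix)
        if _have(strain="sexual", irradiation="IR", population="whole") and _have(
            strain="asexual", irradiation="IR", population="whole"
        ):
            irr_table = classify_irradiation_table(matrix)
            irr_table.to_csv(out / "irradiation.tsv", sep="\t")
            report.outputs["irradiation"] = str(out / "irradiation.tsv")
            report.headline["irradiation_counts"] = (
                irr_table["call"].value_counts().to_dict()
            )
        if all(_have(population=p) for p in ("X1", "X2", "Xins")):
            enr_table = classify_cell_enrichment_table(matrix, presence=config.min_fpkm)
            enr_table.to_csv(out / "cell_enrichment.tsv", sep="\t")
            report.outputs["cell_enrichment"] = str(out / "cell_enrichment.tsv")
            report.headline["cell_enrichment_counts"] = (
                enr_table["enriched_in"].value_counts().to_dict()
            )
            report.headline["population_overlap"] = population_overlap(
                matrix, presence=config.min_fpkm
            )
        if _have(population="hESC") and _have(population="hEB"):
            hesc_table = classify_hesc_table(matrix, fold=config.hesc_fold)
            hesc_table.to_csv(out / "hesc_enrichment.tsv", sep="\t")
            report.outputs["hesc_enrichment"] = str(out / "hesc_enrichment.tsv")
            report.headline["hesc_counts"] = hesc_table["call"].value_counts().to_dict()
        zscores, constant = zscore_rows(matrix)
        zscores.to_csv(out / "zscores.tsv", sep="\t", float_format="%.6g")
        report.outputs["zscores"] = str(out / "zscores.tsv")
    else:
        report.skipped.append("expression")
        logger.info("[expression] matrix/samples missing; skipping")

    if config.forward_hits is not None and config.reverse_hits is not None:
        logger.info("[orthology] computing reciprocal best hits")
        fwd = best_hits(read_hit_table(config.forward_hits), config.homolog_evalue)
        rev = best_hits(read_hit_table(config.reverse_hits), config.homolog_evalue)
        pairs = reciprocal_best_hits(fwd, rev)
        write_pairs_tsv(pairs, out / "ortholog_pairs.tsv")
        report.outputs["ortholog_pairs"] = str(out / "ortholog_pairs.tsv")
        report.headline["ortholog_pairs"] = len(pairs)
        if config.class_a is not None and config.class_b is not None:
            class_a = _read_class_map(config.class_a)
            class_b = _read_class_map(config.class_b)
            table = conserved_enrichment(pairs, class_a, class_b)
            (out / "conservation.json").write_text(
                json.dumps(table.to_dict(), indent=2) + "\n"
            )
            report.outputs["conservation"] = str(out / "conservation.json")
            report.headline["conserved_stem"] = table.conserved_stem
            report.headline["conserved_diff"] = table.conserved_diff
            d_x1 = table.denominators.get("X1", 0)
            d_xins = table.denominators.get("Xins", 0)
            if d_x1 and d_xins:
                z = two_proportion_ztest(
                    table.conserved_stem, d_x1, table.conserved_diff, d_xins
                )
                report.headline["conservation_ztest"] = z
    else:
        report.skipped.append("orthology")
        logger.info("[orthology] hit tables missing; skipping")

    if (
        config.domain_hits is not None
        and config.go_map is not None
        and config.target_ids is not None
        and config.control_ids is not None
    ):
        logger.info("[enrichment] GO category enrichment")
        hits = filter_domain_hits(
            read_domain_hits(config.domain_hits),
            max_evalue=config.domain_evalue,
            min_coverage=config.domain_coverage,
        )
        assignments = transfer_go(hits, read_go_map(config.go_map))
        target = set(Path(config.target_ids).read_text().split())
        control = set(Path(config.control_ids).read_text().split())
        results = go_enrichment(target, control, assignments)
        write_enrichment_tsv(results, out / "go_enrichment.tsv")
        report.outputs["go_enrichment"] = str(out / "go_enrichment.tsv")
        if results:
            top = results[0]
            report.headline["top_enriched_category"] = {
                "category": top.category,
                "p_bonferroni": top.p_bonferroni,
            }
    else:
        report.skipped.append("enrichment")
        logger.info("[enrichment] domain/GO inputs missing; skipping")

    report.write(out)
    return report


def _read_class_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or (i == 0 and line.startswith("gene_id")):
            continue
        gene, cls = line.split("\t")[:2]
        if cls:
            out[gene] = cls
    return out


def _read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader (sequences used for composition only)."""
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}
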