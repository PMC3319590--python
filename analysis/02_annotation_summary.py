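#!/usr/bin/env python
"""Summarize the transcript models: counts, mean lengths, footprints.

Reads results/synthetic/annotation.gtf, derives introns, and writes the
genome-annotation summary (gene/transcript/exon/intron counts, mean gene
span and transcript length, transcribed and exonic footprints) as TSV and
JSON under results/.
"""

import argparse
from pathlib import Path

from stemtx.transcript_models import read_gtf, summarize_annotation

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--gtf", type=Path, default=Path("results/synthetic/annotation.gtf"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

annotation = read_gtf(args.gtf)
summary = summarize_annotation(annotation)
args.out.mkdir(parents=True, exist_ok=True)
summary.to_tsv(args.out / "annotation_summary.tsv")
summary.to_json(args.out / "annotation_summary.json")

print(f"{summary.gene_count} genes, {summary.transcript_count} transcripts")
print(f"{summary.exon_count} exons (mean {summary.mean_exon_length_bp:.1f} bp), "
      f"{summary.intron_count} introns (mean {summary.mean_intron_length_bp:.1f} bp)")
print(f"mean gene span {summary.mean_gene_span_bp / 1000:.1f} kb; "
      f"mean transcript length {summary.mean_transcript_length_bp:.1f} bp; "
      f"{summary.mean_exon_count:.1f} exons per transcript")
print(f"transcribed footprint {summary.transcribed_footprint_bp:,} bp; "
      f"exonic footprint {summary.exonic_footprint_bp:,} bp")
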