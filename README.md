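# stemtx

Downstream transcriptome analysis for the planarian *Schmidtea mediterranea*
stem-cell system: alternative-splicing event detection from de-novo
transcript models, FPKM-based classification of strain bias, irradiation
sensitivity and cell-population enrichment, reciprocal-best-hit orthology
against human, and cross-species conserved-stemness statistics — all
exercised end to end on synthetic inputs with planted ground truth.

## Who this is for

Planarians regenerate through neoblasts, their only proliferating somatic
cells, which are depleted by γ-irradiation and can be FACS-sorted into
proliferating neoblasts (X1), G1-phase progeny (X2), and differentiated
cells (Xins). Given transcript models assembled from RNA-Seq and FPKM
expression tables for sexual/asexual strains (± irradiation), sorted cell
populations, and a human hESC/hEB contrast, this package performs every
classification and statistical step that turns those tables into biology:
which transcripts are spliced alternatively and whether the variable exons
preserve reading frame, which transcripts are strain-biased or
neoblast-enriched, and whether stemness expression is conserved between
planarian neoblasts and human embryonic stem cells.

Read alignment, transcript assembly, and FPKM estimation are upstream tools'
jobs; this package consumes their outputs (GTF, TSV matrices, tabular
alignment hits) or generates statistically faithful synthetic stand-ins.

## The methods at the core

* **Splicing events.** Two isoforms of one gene that differ between shared
  splice sites define an event: cassette exons (internal exon cleanly
  skipped by a single junction), retained introns, mutually exclusive exons
  (strict: every flank-spanning isoform carries exactly one), and
  alternative 5′/3′ splice sites (one shared intron boundary, roles
  following strand). Events are deduplicated by (class, variable-region
  coordinates, strand). An exon of length ℓ has phase ℓ mod 3; phase 0 is
  in-frame. Cassette-vs-constitutive frame bias is tested with a 2×2
  Pearson χ² without continuity correction.
* **Expression classes.** A transcript is expressed at FPKM > 1. Strain
  bias at fold ≥ 1.25 gives five categories (specific/biased per strain,
  unbiased); irradiation sensitivity is a strict decrease after irradiation
  in both strains; population enrichment is the strict argmax over
  X1/X2/Xins; human stemness uses hESC ≥ 1.3 × hEB (and conversely).
  Supporting statistics: Pearson r on log₂(1+FPKM), Mann–Whitney U
  (exact for small samples), one-way ANOVA with Tukey HSD and Student t,
  row Z-scores with sample SD.
* **Orthology and conservation.** Reciprocal best hits on tabular alignment
  tables at e-value ≤ 1e-10 (ties: bit score, then subject id). Conserved
  stemness = ortholog pairs X1-enriched in planarian and hESC-enriched in
  human; proportions are compared with the pooled two-proportion Z test
  z = (p̂₂ − p̂₁)/√(p̂(1−p̂)(1/n₁+1/n₂)).
* **Annotation.** Homolog filter e ≤ 1e-10; domain filter e ≤ 1e-3 with
  ≥ 80% domain coverage; flat GO transfer from accepted domains; category
  enrichment by χ² with Bonferroni correction (Fisher fallback for small
  expected counts).

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1   # study-scale synthetic bundle
python analysis/03_splicing_events.py
python analysis/05_orthology_conservation.py
```

prints (seed 1):

```
events detected (genes):
  cassette               512 (512)
  retained_intron        286 (286)
  mutually_exclusive      36 (36)
  alt5ss                 113 (113)
  alt3ss                  88 (88)
  total 1035 events in 1035 genes
planted-event recovery exact: True
in-frame: 74% of 512 cassette exons vs 34% of 1663 constitutive exons
  (chi2 = 254.7, p = 2.49e-57)

1729 reciprocal-best-hit ortholog pairs (from 3396 forward / 3396 reverse best hits)
conserved stem (X1 & hESC): 95/455
conserved differentiated (Xins & hEB): 123/397
two-proportion Z test: z = 3.37, p = 0.00075
```

Every planted event is recovered exactly once; cassette exons show the
strong in-frame bias absent from constitutive exons; of 1,729 ortholog
pairs, the X1∩hESC conserved fraction (95/455) is significantly smaller
than the Xins∩hEB fraction (123/397). The remaining drivers
(`02_annotation_summary.py`, `04_expression_classification.py`,
`06_go_enrichment.py`) summarize the gene models, classify the expression
matrix (89% unbiased / 6% specific / 5% biased; 28% irradiation-sensitive;
73% of expressed transcripts present in all three cell populations), and
rank GO-category enrichment. The same functionality is exposed as a CLI
(`stemtx synth|annotate-summary|splice-events|classify|orthology|enrich|run`).

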