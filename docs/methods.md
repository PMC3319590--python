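# Methods

## Coordinate model

All in-memory coordinates are 0-based half-open; GTF on disk is 1-based
inclusive and converted at the I/O boundary, so lengths are always
`end − start`. Genes come pre-grouped by `gene_id` (no re-clustering of
overlapping transcripts: the assembler that produced the models already
grouped them). Introns are the gaps between consecutive exons of one
transcript; a transcript's length is its exonic (mature) length. Exon and
intron counts in the annotation summary are totals over transcript records
— an exon shared by two isoforms counts twice — which is the convention
that makes (mean exons per transcript) × (transcripts) ≈ (exon count).
Footprints are per-contig interval unions: gene spans for the transcribed
footprint, exon intervals for the exonic footprint. GC content is
(G+C)/(A+C+G+T) with N excluded from the denominator, so assembly gap runs
do not dilute composition. The expression percentile of a threshold t is
100 × P(FPKM ≤ t), the inclusive reading under which a cutoff "FPKM > t"
keeps the mass above the reported percentile.

## Splicing-event detection

Events are extracted from every ordered isoform pair of a gene and
deduplicated gene-wide by (class, sorted variable-region coordinates,
strand), so one variable region seen in many isoform pairs is one event.
Rules:

* **Cassette** — internal exon E of isoform A whose flanking splice sites
  (upstream donor d, downstream acceptor a) appear in isoform B as a single
  intron (d, a). Terminal exons never qualify: alternative transcription
  start or polyadenylation is not splicing.
* **Retained intron** — intron of A contained in one exon of B whose
  boundaries equal the outer boundaries of A's flanking exons. The
  "inclusion" side is the isoform whose mature transcript contains the
  intron.
* **Mutually exclusive** — two non-overlapping internal exons between
  identical flanks (d, a) such that every isoform spanning those flanks
  (an exon ending at d and an exon starting at a) contains exactly one of
  the two, where "contains" means exon membership anywhere in the isoform.
  This strict reading makes "mutually exclusive" well defined: a skipping
  isoform (neither exon) or a double-inclusion isoform disqualifies the
  pair, and the structures decay to cassette events instead.
* **Alternative 5′/3′ splice sites** — two introns sharing exactly one
  boundary; the segment between the differing boundaries must be exonic in
  the isoform with the longer exon (otherwise the configuration is exon
  skipping seen from the junction side, which must not fire). On the minus
  strand the intron-start boundary is the acceptor, so the class assignment
  flips with strand; reflecting a gene's coordinates and flipping strand
  maps each class to itself, a property the tests check.

Exon pairs that overlap with both boundaries different fit none of the
five classes; they are reported on a diagnostic "complex" channel
(`emit_complex`) and excluded from event summaries.

Constitutive exons — the comparison set for frame bias — are internal exons
whose exact coordinates appear in every isoform of their gene, including
single-isoform genes (where the condition is vacuous). This maximizes the
genome-wide constitutive denominator. Frame bias uses the 2×2 χ² without
continuity correction (the comparison has large counts; a flag marks
expected cells below 1 rather than switching tests).

The detector is validated against an independent brute-force enumerator
that tests every exon/intron/junction combination with per-base set
arithmetic, on 500 random multi-isoform genes built by perturbing a master
exon chain (drops, merges, boundary jitter), plus a strand-reflection
property test.

## Expression classification

"Expressed" is FPKM strictly greater than a presence threshold (default
1.0) everywhere. Strain bias: both strains off → unexpressed; exactly one
on → that strain's *specific* call (the presence threshold operationalizes
"uniquely expressed", which the qualitative description leaves open); both
on → *biased* when the larger/smaller ratio is ≥ 1.25 (inclusive, on raw
FPKM — both values already exceed the presence floor, so no pseudocount is
needed), else *unbiased*. Irradiation sensitivity is any strict decrease
after irradiation in both strains, with no magnitude floor. Population
enrichment is the strict argmax over X1/X2/Xins; ties are reported
unclassified rather than broken arbitrarily. Human stemness: hESC ≥ 1.3 ×
hEB (inclusive) with a positive value against zero counting as enriched
and both-zero as neither. Z-scores use the sample SD (n−1); constant rows
become zero rows with a flag so exports stay rectangular.

Mann–Whitney U uses the exact null for combined n ≤ 20 without ties and
the tie-corrected normal approximation otherwise (needed for the
astronomically small p-values that arise at transcriptome scale). The
population comparison reports one-way ANOVA, Tukey HSD, and pairwise
Student t (equal variance) — the classical validation trio for the
three-population design.

## Orthology and conservation

Best hits are selected at e-value ≤ 1e-10 with a deterministic tie chain
(lower e-value, then higher bit score, then lexicographic subject id);
reciprocal best hits form a matching, and symmetry of the construction is
property-tested. Transcript-level hits can be collapsed to genes before
RBH (`collapse_to_genes`), matching gene-level ortholog counting.
Conservation cross-tabulates per-species enrichment classes over pairs
with both genes classified; denominators are per species-A class, the
reading of "normalizing for total orthologous gene pairs" consistent with
comparing 95/455 against 123/397. The two-proportion Z test uses the
pooled variance and a two-sided normal p computed via erfc for tail
precision; a degenerate pooled proportion (0 or 1) returns p = 1 with a
flag.

## Annotation filters and enrichment

Homolog hits pass at e ≤ 1e-10; when several subjects tie at the minimal
e-value all are reported (multi-species ties carry information). Domain
hits pass at e ≤ 1e-3 **and** coverage ≥ 0.80, both boundaries inclusive.
GO terms transfer flat from accepted domains (no ancestor propagation),
and a transcript counts once per category regardless of how many of its
domains carry the term — the conservative counting unit. Enrichment is a
2×2 χ² without continuity correction, Bonferroni-corrected over the
categories actually tested in the run (not a global GO-universe size);
when any expected cell is below 5 the p-value comes from Fisher's exact
test and the result is flagged.

## Synthetic data: what it emulates and what it does not

The generators plant machine-readable truth and place every entity
strictly inside its category region with a small relative safety margin
(default 1e-3) away from each threshold, so rule-based classifiers must
recover 100% of labels — a miss is a bug, not noise. One global seed
drives independent numpy substreams per generator
(`default_rng([seed, stream])`), making bundles byte-identical across
runs.

Defaults are the study conditions: 512/286/36/113/88 planted events of the
five classes (one event per gene, realized by exactly the isoform pair the
definition requires); exon and intron lengths log-normal with means ≈ 272
and ≈ 2,668 bp; in-frame probabilities 0.73 (cassette), 0.35
(constitutive), 0.39 (retained); bias fractions 0.89/0.06/0.05 with a 0.92
sexual share of the biased/specific side; 28% irradiation-sensitive;
X1/X2/Xins Venn-region counts matching the reported overlap structure
(10,657 in all three, 252/368/878 population-specific, out of 14,522
expressed); 1,729 ortholog pairs with 455 X1- and 397 Xins-classified and
95/123 conserved partners, plus 5,000 asymmetric or dominated decoy hits;
a GO category planted at 0.4 target vs 0.05 control frequency. The default
expression matrix size is 17,084 rows (the irradiation universe); analyses
that the study ran on other universes (12,088 bias-classified transcripts)
pass the size explicitly. FPKM values are log-normal — no distribution is
prescribed anywhere, and the heavy right tail is consistent with a
presence cutoff sitting at a high percentile of the full transcript
distribution (the `sample_fpkm_mixture` helper models that full mixture,
92% of mass at or below FPKM 1).

What passing these tests shows: the classification rules, event
definitions, and statistics are implemented exactly as specified. What it
does not show: robustness to the noise structure of real RNA-Seq —
assembly artifacts, FPKM estimation error, biological replication (the
emulated design has none), or borderline values sitting on thresholds.
The separate correlated-FPKM generator targets a log-space Pearson r
(default 0.92) for the strain-correlation check; the planted-bias matrix
itself makes no correlation claim.

## Numerical and degenerate-input choices

χ² tables with an empty margin return (0, 1) instead of NaN; identical
constant ANOVA groups likewise. Zero-variance columns abort the
correlation with an error rather than returning NaN. The percentile and
presence comparisons are strict or inclusive exactly as stated above, and
the generators' safety margins keep tests off the floating-point knife
edge. Transcripts spanning multiple contigs or strands, overlapping exons,
and malformed GTF lines are hard errors naming the offending record.

## Problem sizes

The test suite runs study-scale checks where the quantity depends on scale
(12,088-row bias matrix, 17,084-row irradiation matrix, 1,729-pair
orthology, 500 random genes against the brute-force oracle, 10,000
two-proportion null replicates, 1,000 Bonferroni familywise replicates)
and down-scaled bundles (≈ 65 event genes, 2,500-row matrices) everywhere
exactness, not scale, is under test. The full suite completes in well
under a minute on one CPU; `scripts/acceptance.py` in a few seconds.

## Known limitations

* Event inclusion levels (PSI) and read-based strain-specific splicing are
  out of scope; detection is purely structural from transcript models.
* GO transfer is flat; no ontology-graph propagation.
* The constitutive-exon universe (and hence the constitutive in-frame
  fraction) depends on the annotation supplied; it has no single canonical
  definition.
* Hierarchical clustering / heat-map rendering are not included; the
  package exports Z-score matrices for external tools.
* The upstream counts it consumes (exon totals, transcript universes)
  are taken as given; small inconsistencies between alternative printed
  versions of such totals are inherited, not adjudicated.
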