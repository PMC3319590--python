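"""Expression-based classification of transcripts from FPKM matrices.

Covers the three classification axes of the study design:

* strain bias — sexual vs asexual whole-animal FPKM, five categories at a
  1.25-fold threshold plus an ``unexpressed`` bucket;
* irradiation sensitivity — strict decrease after irradiation in both
  strains (gamma-irradiation depletes neoblasts, so decreased transcripts
  proxy neoblast expression);
* cell-population enrichment — argmax over FACS-sorted X1 (proliferating
  neoblasts), X2 (neoblast progeny) and Xins (differentiated) fractions,
  plus the human hESC/hEB contrast at a 1.3-fold threshold.

"Expressed" always means FPKM strictly greater than a presence threshold
(default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "BiasCall",
    "EnrichmentCall",
    "BIAS_CATEGORIES",
    "filter_expressed",
    "classify_strain_bias",
    "classify_irradiation",
    "classify_cell_enrichment",
    "classify_hesc_enrichment",
    "population_overlap",
    "zscore_rows",
    "strain_correlation",
    "bias_distribution_test",
    "population_anova",
    "read_expression",
    "classify_strain_bias_table",
    "classify_irradiation_table",
    "classify_cell_enrichment_table",
    "classify_hesc_table",
]

BIAS_CATEGORIES = (
    "asexual_specific",
    "asexual_biased",
    "unbiased",
    "sexual_biased",
    "sexual_specific",
    "unexpressed",
)

VENN_REGIONS = ("X1", "X2", "Xins", "X1_X2", "X1_Xins", "X2_Xins", "X1_X2_Xins")


@dataclass(frozen=True)
class SampleMeta:
    name: str
    strain: str = "none"  # sexual | asexual | human | none
    irradiation: str = "none"  # NIR | IR | none
    population: str = "whole"  # whole | X1 | X2 | Xins | hESC | hEB

    def __post_init__(self):
        if self.population == "whole" and self.strain not in ("sexual", "asexual"):
            raise ValueError(
                f"sample {self.name}: whole-animal samples need a planarian strain"
            )


@dataclass
class ExpressionMatrix:
    """Transcript x sample FPKM matrix with per-sample metadata."""

    values: pd.DataFrame  # index: transcript ids; columns: sample names
    samples: list[SampleMeta]

    def __post_init__(self):
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        if list(self.values.columns) != names:
            raise ValueError("matrix columns must match sample metadata order")
        if self.values.index.has_duplicates:
            raise ValueError("transcript ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    def sample(self, name: str) -> SampleMeta:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)

    def column_for(self, **criteria) -> str:
        """Name of the unique sample matching the metadata criteria."""
        matches = [
            s.name
            for s in self.samples
            if all(getattr(s, k) == v for k, v in criteria.items())
        ]
        if len(matches) != 1:
            raise KeyError(f"expected one sample matching {criteria}, got {matches}")
        return matches[0]

    @property
    def n_transcripts(self) -> int:
        return len(self.values)

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.6g")
        meta = pd.DataFrame(
            {
                "name": [s.name for s in self.samples],
                "strain": [s.strain for s in self.samples],
                "irradiation": [s.irradiation for s in self.samples],
                "population": [s.population for s in self.samples],
            }
        )
        meta.to_csv(samples_path, sep="\t", index=False)


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM matrix TSV plus its sidecar sample-metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t", dtype=str)
    samples = [
        SampleMeta(r["name"], r["strain"], r["irradiation"], r["population"])
        for _, r in meta.iterrows()
    ]
    return ExpressionMatrix(values[[s.name for s in samples]], samples)


@dataclass(frozen=True)
class BiasCall:
    transcript_id: str
    category: str
    fold_change: float | None  # larger/smaller; None when a strain is off


@dataclass(frozen=True)
class EnrichmentCall:
    transcript_id: str
    enriched_in: str  # X1 | X2 | Xins | unclassified
    specific_to: str | None
    expressed_in: frozenset[str]


# ---------------------------------------------------------------------------
# Filters and scalar classifiers
# ---------------------------------------------------------------------------

def filter_expressed(
    matrix: ExpressionMatrix,
    min_fpkm: float = 1.0,
    mode: Literal["any_sample", "all_samples"] = "any_sample",
) -> ExpressionMatrix:
    """Keep rows with FPKM strictly above ``min_fpkm`` in any/all samples."""
    arr = matrix.values.to_numpy() > min_fpkm
    keep = arr.any(axis=1) if mode == "any_sample" else arr.all(axis=1)
    return ExpressionMatrix(matrix.values.loc[keep].copy(), list(matrix.samples))


def classify_strain_bias(
    sexual_fpkm: float,
    asexual_fpkm: float,
    fold: float = 1.25,
    presence: float = 1.0,
    transcript_id: str = "",
) -> BiasCall:
    """Five-way strain-bias call for one transcript.

    A strain expresses the transcript when its FPKM exceeds ``presence``.
    Both off -> unexpressed; exactly one on -> that strain's _specific;
    both on with ratio (larger/smaller) >= ``fold`` (inclusive) -> the
    larger strain's _biased; otherwise unbiased.
    """
    if fold <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {fold}")
    sex_on = sexual_fpkm > presence
    asex_on = asexual_fpkm > presence
    if not sex_on and not asex_on:
        return BiasCall(transcript_id, "unexpressed", None)
    if sex_on and not asex_on:
        return BiasCall(transcript_id, "sexual_specific", None)
    if asex_on and not sex_on:
        return BiasCall(transcript_id, "asexual_specific", None)
    hi, lo = max(sexual_fpkm, asexual_fpkm), min(sexual_fpkm, asexual_fpkm)
    ratio = hi / lo
    if ratio >= fold:
        cat = "sexual_biased" if sexual_fpkm > asexual_fpkm else "asexual_biased"
        return BiasCall(transcript_id, cat, ratio)
    return BiasCall(transcript_id, "unbiased", ratio)


def classify_irradiation(
    nir_sexual: float, ir_sexual: float, nir_asexual: float, ir_asexual: float
) -> str:
    """'sensitive' iff expression strictly decreases after irradiation in
    both strains; otherwise 'insensitive'."""
    return (
        "sensitive"
        if (ir_sexual < nir_sexual and ir_asexual < nir_asexual)
        else "insensitive"
    )


def classify_cell_enrichment(
    x1: float, x2: float, xins: float, presence: float = 1.0, transcript_id: str = ""
) -> EnrichmentCall:
    """Cell-population call: enrichment by strict argmax, specificity by
    sole presence above the threshold. Ties are left unclassified."""
    values = {"X1": x1, "X2": x2, "Xins": xins}
    top = max(values.values())
    winners = [k for k, v in values.items() if v == top]
    enriched = winners[0] if len(winners) == 1 else "unclassified"
    expressed = frozenset(k for k, v in values.items() if v > presence)
    specific = next(iter(expressed)) if len(expressed) == 1 else None
    return EnrichmentCall(transcript_id, enriched, specific, expressed)


def classify_hesc_enrichment(
    hesc_fpkm: float, heb_fpkm: float, fold: float = 1.3
) -> str:
    """Human stemness call at a fold threshold (inclusive >=).

    A positive value against a zero counts as enriched; both zero is
    'neither'.
    """
    if hesc_fpkm == 0 and heb_fpkm == 0:
        return "neither"
    if hesc_fpkm > 0 and (heb_fpkm == 0 or hesc_fpkm >= fold * heb_fpkm):
        return "hESC_enriched"
    if heb_fpkm > 0 and (hesc_fpkm == 0 or heb_fpkm >= fold * hesc_fpkm):
        return "hEB_enriched"
    return "neither"


# ---------------------------------------------------------------------------
# Matrix-level operations
# ---------------------------------------------------------------------------

def population_overlap(
    matrix: ExpressionMatrix, presence: float = 1.0
) -> dict[str, int]:
    """Venn accounting of expression across the X1/X2/Xins populations.

    Returns the seven non-empty region counts plus ``total`` (expressed in
    at least one population). Requires exactly one sample per population.
    """
    cols = {}
    for pop in ("X1", "X2", "Xins"):
        try:
            cols[pop] = matrix.column_for(population=pop)
        except KeyError as exc:
            raise ValueError(f"matrix lacks a unique {pop} sample") from exc
    on = {p: matrix.values[c].to_numpy() > presence for p, c in cols.items()}
    regions = {
        "X1": on["X1"] & ~on["X2"] & ~on["Xins"],
        "X2": ~on["X1"] & on["X2"] & ~on["Xins"],
        "Xins": ~on["X1"] & ~on["X2"] & on["Xins"],
        "X1_X2": on["X1"] & on["X2"] & ~on["Xins"],
        "X1_Xins": on["X1"] & ~on["X2"] & on["Xins"],
        "X2_Xins": ~on["X1"] & on["X2"] & on["Xins"],
        "X1_X2_Xins": on["X1"] & on["X2"] & on["Xins"],
    }
    counts = {k: int(v.sum()) for k, v in regions.items()}
    counts["total"] = int((on["X1"] | on["X2"] | on["Xins"]).sum())
    return counts


def zscore_rows(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z-scores: (x - row mean) / row sample SD (ddof = 1).

    Constant rows map to all-zero rows and are flagged (second return value)
    rather than producing NaNs, keeping exports rectangular.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("Z-scores need at least two samples")
    arr = matrix.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (arr - mean) / sd
    z[constant, :] = 0.0
    zdf = pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    return zdf, pd.Series(constant, index=matrix.values.index, name="constant_row")


def strain_correlation(matrix: ExpressionMatrix) -> float:
    """Pearson r between sexual-NIR and asexual-NIR samples on log2(1+FPKM)."""
    if matrix.n_transcripts < 3:
        raise ValueError("correlation needs at least 3 transcripts")
    sex = matrix.values[matrix.column_for(strain="sexual", irradiation="NIR", population="whole")]
    asex = matrix.values[matrix.column_for(strain="asexual", irradiation="NIR", population="whole")]
    x = np.log2(1.0 + sex.to_numpy(dtype=float))
    y = np.log2(1.0 + asex.to_numpy(dtype=float))
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a strain column")
    return float(stats.pearsonr(x, y).statistic)


def bias_distribution_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney U p-value comparing two FPKM distributions.

    Exact null distribution for combined n <= 20 without ties; otherwise the
    tie-corrected normal approximation (which handles astronomically small
    p-values via the log-space survival function).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def population_anova(
    x1_values: Sequence[float],
    x2_values: Sequence[float],
    xins_values: Sequence[float],
) -> dict:
    """One-way ANOVA across the three populations, plus pairwise Tukey HSD
    and Student t-tests (equal variance), mirroring the classification
    validation design."""
    groups = [np.asarray(g, dtype=float) for g in (x1_values, x2_values, xins_values)]
    names = ("X1", "X2", "Xins")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name} needs at least 2 values")
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
        if np.isnan(f_stat):  # identical constant groups
            f_stat, p = 0.0, 1.0
    tukey = stats.tukey_hsd(*groups)
    pairs = [(0, 1), (0, 2), (1, 2)]
    tukey_pairwise = {}
    t_pairwise = {}
    for i, j in pairs:
        label = f"{names[i]}_vs_{names[j]}"
        tukey_pairwise[label] = {
            "diff": float(groups[i].mean() - groups[j].mean()),
            "p": float(tukey.pvalue[i, j]),
        }
        t_stat, t_p = stats.ttest_ind(groups[i], groups[j], equal_var=True)
        if np.isnan(t_stat):
            t_stat, t_p = 0.0, 1.0
        t_pairwise[label] = {"t": float(t_stat), "p": float(t_p)}
    return {
        "F": float(f_stat),
        "p": float(p),
        "tukey_pairwise": tukey_pairwise,
        "t_pairwise": t_pairwise,
    }


# ---------------------------------------------------------------------------
# Whole-table classification helpers
# ---------------------------------------------------------------------------

def classify_strain_bias_table(
    matrix: ExpressionMatrix, fold: float = 1.25, presence: float = 1.0
) -> pd.DataFrame:
    """Strain-bias calls for every row, from the two NIR whole-animal samples."""
    sex_col = matrix.column_for(strain="sexual", irradiation="NIR", population="whole")
    asex_col = matrix.column_for(strain="asexual", irradiation="NIR", population="whole")
    rows = []
    for tid, sex, asex in zip(
        matrix.values.index, matrix.values[sex_col], matrix.values[asex_col]
    ):
        call = classify_strain_bias(sex, asex, fold=fold, presence=presence, transcript_id=tid)
        rows.append((tid, sex, asex, call.category, call.fold_change))
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "sexual_fpkm", "asexual_fpkm", "category", "fold_change"],
    ).set_index("transcript_id")


def classify_irradiation_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Irradiation-sensitivity calls from the four whole-animal samples."""
    cols = {
        (st, irr): matrix.column_for(strain=st, irradiation=irr, population="whole")
        for st in ("sexual", "asexual")
        for irr in ("NIR", "IR")
    }
    v = matrix.values
    calls = [
        classify_irradiation(ns, is_, na, ia)
        for ns, is_, na, ia in zip(
            v[cols[("sexual", "NIR")]],
            v[cols[("sexual", "IR")]],
            v[cols[("asexual", "NIR")]],
            v[cols[("asexual", "IR")]],
        )
    ]
    return pd.DataFrame({"call": calls}, index=v.index)


def classify_cell_enrichment_table(
    matrix: ExpressionMatrix, presence: float = 1.0
) -> pd.DataFrame:
    """Enrichment/specificity calls from the X1/X2/Xins samples."""
    cols = {p: matrix.column_for(population=p) for p in ("X1", "X2", "Xins")}
    v = matrix.values
    rows = []
    for tid, x1, x2, xins in zip(v.index, v[cols["X1"]], v[cols["X2"]], v[cols["Xins"]]):
        call = classify_cell_enrichment(x1, x2, xins, presence=presence, transcript_id=tid)
        rows.append(
            (
                tid,
                call.enriched_in,
                call.specific_to or "",
                ",".join(sorted(call.expressed_in)),
            )
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "enriched_in", "specific_to", "expressed_in"]
    ).set_index("transcript_id")


def classify_hesc_table(matrix: ExpressionMatrix, fold: float = 1.3) -> pd.DataFrame:
    """hESC/hEB enrichment calls from the two human samples."""
    hesc = matrix.column_for(population="hESC")
    heb = matrix.column_for(population="hEB")
    calls = [
        classify_hesc_enrichment(a, b, fold=fold)
        for a, b in zip(matrix.values[hesc], matrix.values[heb])
    ]
    return pd.DataFrame({"call": calls}, index=matrix.values.index)
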