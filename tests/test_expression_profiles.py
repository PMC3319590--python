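import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import exhaustive_mannwhitney_pvalue, permutation_two_sample_pvalue
from stemtx.expression_profiles import (
    BIAS_CATEGORIES,
    ExpressionMatrix,
    SampleMeta,
    bias_distribution_test,
    classify_cell_enrichment,
    classify_hesc_enrichment,
    classify_irradiation,
    classify_irradiation_table,
    classify_strain_bias,
    classify_strain_bias_table,
    filter_expressed,
    population_anova,
    population_overlap,
    strain_correlation,
    zscore_rows,
)
from stemtx.synthetic_data import (
    SynthConfig,
    generate_correlated_fpkm,
    generate_expression,
)


def _matrix(values: dict[str, list[float]], metas: list[SampleMeta]) -> ExpressionMatrix:
    df = pd.DataFrame(values)
    df.index = [f"t{i}" for i in range(len(df))]
    return ExpressionMatrix(df, metas)


class TestFilterExpressed:
    def test_strict_inequality_at_threshold(self):
        m = _matrix(
            {"a": [1.0, 0.0, 1.5], "b": [1.0, 5.0, 0.2]},
            [SampleMeta("a", "sexual"), SampleMeta("b", "asexual")],
        )
        assert list(filter_expressed(m).values.index) == ["t1", "t2"]
        assert list(filter_expressed(m, mode="all_samples").values.index) == []

    def test_retained_fraction_tracks_planted_mixture(self):
        from stemtx.synthetic_data import sample_fpkm_mixture

        values = sample_fpkm_mixture(10_000, seed=9, frac_below=0.4)
        m = _matrix(
            {"a": values, "b": np.zeros(10_000)},
            [SampleMeta("a", "sexual"), SampleMeta("b", "asexual")],
        )
        frac = filter_expressed(m).n_transcripts / 10_000
        assert abs(frac - 0.6) < 0.02


class TestStrainBias:
    @pytest.mark.parametrize(
        "sex,asex,category",
        [
            (10.0, 0.0, "sexual_specific"),
            (2.5, 2.0, "sexual_biased"),  # ratio exactly 1.25, inclusive
            (2.4, 2.0, "unbiased"),  # ratio 1.20
            (0.0, 10.0, "asexual_specific"),
            (0.5, 0.5, "unexpressed"),
        ],
    )
    def test_category_examples(self, sex, asex, category):
        assert classify_strain_bias(sex, asex).category == category

    def test_fold_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            classify_strain_bias(1, 2, fold=1.0)

    @given(
        st.floats(0, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        swap = {
            "sexual_specific": "asexual_specific",
            "asexual_specific": "sexual_specific",
            "sexual_biased": "asexual_biased",
            "asexual_biased": "sexual_biased",
            "unbiased": "unbiased",
            "unexpressed": "unexpressed",
        }
        assert classify_strain_bias(b, a).category == swap[
            classify_strain_bias(a, b).category
        ]

    def test_categories_partition_matrix(self, small_expression):
        matrix, _ = small_expression
        table = classify_strain_bias_table(matrix)
        counts = table["category"].value_counts()
        assert counts.sum() == matrix.n_transcripts
        assert set(counts.index) <= set(BIAS_CATEGORIES)

    def test_planted_fractions_recovered(self):
        cfg = SynthConfig(seed=31, n_transcripts_expression=10_000)
        matrix, truth = generate_expression(cfg)
        table = classify_strain_bias_table(matrix)
        assert (table["category"] == truth["bias_category"]).all()
        frac_unbiased = (table["category"] == "unbiased").mean()
        assert abs(frac_unbiased - 0.89) < 0.02


class TestIrradiation:
    @pytest.mark.parametrize(
        "vals,expected",
        [
            ((10, 5, 8, 4), "sensitive"),
            ((10, 5, 8, 8), "insensitive"),
            ((10, 10, 8, 4), "insensitive"),
        ],
    )
    def test_strict_decrease_in_both_strains(self, vals, expected):
        assert classify_irradiation(*vals) == expected

    def test_planted_sensitive_fraction_recovered(self, small_expression):
        matrix, truth = small_expression
        table = classify_irradiation_table(matrix)
        assert (table["call"] == truth["irradiation"]).all()
        assert abs((table["call"] == "sensitive").mean() - 0.28) < 0.015


class TestCellEnrichment:
    def test_argmax(self):
        assert classify_cell_enrichment(5, 1, 1).enriched_in == "X1"

    def test_specificity(self):
        call = classify_cell_enrichment(0.5, 0.2, 3.0)
        assert call.enriched_in == "Xins"
        assert call.specific_to == "Xins"
        assert call.expressed_in == {"Xins"}

    def test_tie_unclassified(self):
        assert classify_cell_enrichment(2, 2, 1).enriched_in == "unclassified"


class TestPopulationOverlap:
    def _pop_matrix(self, rows):
        metas = [
            SampleMeta("X1", "sexual", "none", "X1"),
            SampleMeta("X2", "sexual", "none", "X2"),
            SampleMeta("Xins", "sexual", "none", "Xins"),
        ]
        arr = np.array(rows, dtype=float)
        return _matrix(
            {"X1": arr[:, 0], "X2": arr[:, 1], "Xins": arr[:, 2]}, metas
        )

    def test_singletons(self):
        m = self._pop_matrix([[5, 0, 0], [0, 5, 0], [0, 0, 5]])
        counts = population_overlap(m)
        assert counts["X1"] == counts["X2"] == counts["Xins"] == 1
        assert counts["X1_X2_Xins"] == 0
        assert counts["total"] == 3

    def test_everything_everywhere(self):
        m = self._pop_matrix([[5, 5, 5]] * 4)
        counts = population_overlap(m)
        assert counts["X1_X2_Xins"] == 4 and counts["total"] == 4

    def test_regions_partition_total(self, small_expression):
        matrix, truth = small_expression
        counts = population_overlap(matrix)
        region_sum = sum(
            counts[r] for r in ("X1", "X2", "Xins", "X1_X2", "X1_Xins", "X2_Xins", "X1_X2_Xins")
        )
        assert region_sum == counts["total"]
        planted = truth["venn_region"].value_counts()
        for region in ("X1", "X2", "Xins", "X1_X2", "X1_Xins", "X2_Xins", "X1_X2_Xins"):
            assert counts[region] == planted.get(region, 0)

    def test_missing_population_rejected(self):
        m = _matrix(
            {"X1": [1.0], "X2": [1.0]},
            [SampleMeta("X1", "sexual", "none", "X1"), SampleMeta("X2", "sexual", "none", "X2")],
        )
        with pytest.raises(ValueError):
            population_overlap(m)


class TestZScores:
    def _two_sample(self, rows):
        arr = np.asarray(rows, dtype=float)
        metas = [SampleMeta(f"s{i}", "sexual") for i in range(arr.shape[1])]
        return _matrix({f"s{i}": arr[:, i] for i in range(arr.shape[1])}, metas)

    def test_unit_sd_row(self):
        z, flags = zscore_rows(self._two_sample([[1, 2, 3]]))
        assert z.iloc[0].tolist() == [-1.0, 0.0, 1.0]
        assert not flags.iloc[0]

    def test_constant_row_flagged_zero(self):
        z, flags = zscore_rows(self._two_sample([[5, 5, 5]]))
        assert z.iloc[0].tolist() == [0.0, 0.0, 0.0]
        assert bool(flags.iloc[0])

    def test_moments_on_random_rows(self):
        rng = np.random.default_rng(3)
        m = self._two_sample(rng.lognormal(1, 1, size=(50, 8)))
        z, flags = zscore_rows(m)
        assert not flags.any()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_rows(self._two_sample([[1.0]]))


class TestHescEnrichment:
    @pytest.mark.parametrize(
        "hesc,heb,expected",
        [
            (1.3, 1.0, "hESC_enriched"),  # inclusive boundary
            (0.0, 0.0, "neither"),
            (2.0, 0.0, "hESC_enriched"),  # zero-denominator rule
            (1.0, 1.3, "hEB_enriched"),
            (1.2, 1.0, "neither"),
        ],
    )
    def test_examples(self, hesc, heb, expected):
        assert classify_hesc_enrichment(hesc, heb) == expected


class TestStrainCorrelation:
    def _nir_matrix(self, x, y):
        metas = [
            SampleMeta("sex_NIR", "sexual", "NIR", "whole"),
            SampleMeta("asex_NIR", "asexual", "NIR", "whole"),
        ]
        return _matrix({"sex_NIR": x, "asex_NIR": y}, metas)

    def test_identical_columns(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert strain_correlation(self._nir_matrix(x, x)) == pytest.approx(1.0)

    def test_reversed_ordering_negative(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert strain_correlation(self._nir_matrix(x, x[::-1])) < 0

    def test_target_correlation_recovered(self):
        x, y = generate_correlated_fpkm(12_088, target_r=0.92, seed=12)
        r = strain_correlation(self._nir_matrix(x, y))
        assert abs(r - 0.92) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            strain_correlation(self._nir_matrix([1.0, 1.0, 1.0], [1, 2, 3]))


class TestMannWhitney:
    def test_identical_groups(self):
        assert bias_distribution_test([1, 2, 3], [1, 2, 3]) >= 0.99

    def test_small_n_exact_complete_separation(self):
        assert bias_distribution_test([1, 2, 3], [10, 20, 30]) == pytest.approx(0.1)

    def test_exact_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(loc=0.8, size=4)
            p = bias_distribution_test(a, b)
            assert p == pytest.approx(exhaustive_mannwhitney_pvalue(a, b))

    def test_large_n_matches_permutation(self):
        rng = np.random.default_rng(23)
        a = rng.lognormal(0, 1, size=60)
        b = rng.lognormal(0.5, 1, size=70)
        p = bias_distribution_test(a, b)

        def u_stat(x, y):
            return stats.mannwhitneyu(x, y, alternative="two-sided").statistic - len(x) * len(y) / 2

        p_perm = permutation_two_sample_pvalue(a, b, 10_000, seed=5, statistic=u_stat)
        assert abs(p - p_perm) < 3 * np.sqrt(p_perm * (1 - p_perm) / 10_000) + 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bias_distribution_test([], [1.0])


class TestPopulationAnova:
    def test_identical_groups_null(self):
        res = population_anova([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_one_shifted_group(self):
        rng = np.random.default_rng(1)
        base = [0.0, 0.0, 0.0, 0.0]
        shifted = list(10 + rng.normal(0, 1e-3, size=4))
        res = population_anova(base, base, shifted)
        assert res["p"] < 1e-6
        assert res["tukey_pairwise"]["X1_vs_Xins"]["p"] < 0.01
        assert res["tukey_pairwise"]["X2_vs_Xins"]["p"] < 0.01
        assert res["tukey_pairwise"]["X1_vs_X2"]["p"] > 0.5

    def test_power_with_planted_offsets(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(200):
            g1 = rng.normal(0.0, 1, size=40)
            g2 = rng.normal(0.5, 1, size=40)
            g3 = rng.normal(1.2, 1, size=40)
            if population_anova(g1, g2, g3)["p"] < 0.01:
                rejections += 1
        assert rejections >= 190

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            population_anova([1.0], [1, 2], [1, 2])
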