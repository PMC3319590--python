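import numpy as np
import pytest

from stemtx.annotation_enrichment import (
    DomainHit,
    filter_domain_hits,
    filter_homolog_hits,
    go_enrichment,
    domain_frequency,
    transfer_go,
)
from stemtx.orthology_conservation import AlignmentHit
from stemtx.synthetic_data import SynthConfig, generate_domains


class TestHomologFilter:
    def test_boundary_evalue_inclusive(self):
        hits = [AlignmentHit("t1", "s1", 1e-10, 100)]
        assert "t1" in filter_homolog_hits(hits)

    def test_above_threshold_removed(self):
        hits = [AlignmentHit("t1", "s1", 1e-9, 100)]
        assert filter_homolog_hits(hits) == {}

    def test_multiple_species_ties_all_reported(self):
        hits = [
            AlignmentHit("t1", "speciesA", 1e-30, 100),
            AlignmentHit("t1", "speciesB", 1e-30, 90),
            AlignmentHit("t1", "speciesC", 1e-20, 300),
        ]
        best = filter_homolog_hits(hits)["t1"]
        assert {h.subject_id for h in best} == {"speciesA", "speciesB"}


class TestDomainFilter:
    @pytest.mark.parametrize(
        "evalue,coverage,kept",
        [
            (1e-4, 0.85, True),
            (1e-4, 0.79, False),
            (1e-2, 0.95, False),
            (1e-3, 0.80, True),  # both boundaries inclusive
        ],
    )
    def test_joint_thresholds(self, evalue, coverage, kept):
        hits = [DomainHit("t1", "D1", evalue, coverage)]
        assert bool(filter_domain_hits(hits)) is kept

    def test_subset_and_idempotent(self, small_config):
        hits = generate_domains(small_config)["hits"]
        once = filter_domain_hits(hits)
        assert set(once) <= set(hits)
        assert filter_domain_hits(once) == once


class TestTransferGo:
    def test_union_over_domains(self):
        hits = [DomainHit("t1", "D1", 1e-5, 0.9), DomainHit("t1", "D2", 1e-5, 0.9)]
        go = {"D1": frozenset({"GO:a"}), "D2": frozenset({"GO:a", "GO:b"})}
        (a,) = transfer_go(hits, go)
        assert a.go_terms == {"GO:a", "GO:b"}
        assert a.source_domains == {"D1", "D2"}

    def test_unmapped_domain_contributes_nothing(self):
        hits = [DomainHit("t1", "D_unknown", 1e-5, 0.9)]
        assert transfer_go(hits, {"D1": frozenset({"GO:a"})}) == []

    def test_provenance_on_generated_tables(self, small_config):
        data = generate_domains(small_config)
        accepted = filter_domain_hits(data["hits"])
        assignments = transfer_go(accepted, data["go_map"])
        for a in assignments:
            assert a.go_terms
            derived = frozenset().union(
                *(data["go_map"][d] for d in a.source_domains)
            )
            assert a.go_terms == derived

    def test_matches_generator_truth(self, small_config):
        data = generate_domains(small_config)
        accepted = filter_domain_hits(data["hits"])
        assignments = {a.transcript_id: a.go_terms for a in
                       transfer_go(accepted, data["go_map"])}
        for row in data["truth"].itertuples():
            expected = (
                frozenset(row.go_terms.split(",")) if isinstance(row.go_terms, str)
                and row.go_terms else frozenset()
            )
            got = assignments.get(row.transcript_id, frozenset())
            # boundary hits add one extra mapped domain to a few transcripts
            assert expected <= got


class TestDomainFrequency:
    def test_ranking_with_relative_frequency(self):
        hits = [DomainHit("t", "D1", 1e-5, 0.9)] * 3 + [DomainHit("t", "D2", 1e-5, 0.9)]
        assert domain_frequency(hits) == [("D1", 3, 0.75), ("D2", 1, 0.25)]

    def test_empty_input(self):
        assert domain_frequency([]) == []

    def test_lexicographic_tiebreak_and_topn(self):
        hits = [
            DomainHit("t", "DB", 1e-5, 0.9),
            DomainHit("t", "DA", 1e-5, 0.9),
            DomainHit("t", "DC", 1e-5, 0.9),
        ]
        assert [d for d, _, _ in domain_frequency(hits, top_n=2)] == ["DA", "DB"]


class TestGoEnrichment:
    def _assignments(self, spec: dict[str, set[str]]):
        from stemtx.annotation_enrichment import GOAssignment

        return [
            GOAssignment(t, frozenset(gos), frozenset({"D"})) for t, gos in spec.items()
        ]

    def test_complete_separation_closed_form(self):
        target = {f"t{i}" for i in range(50)}
        control = {f"c{i}" for i in range(50)}
        assign = self._assignments({t: {"GO:x"} for t in target})
        (res,) = go_enrichment(target, control, assign)
        assert res.chi2 == pytest.approx(100.0)
        assert res.p_bonferroni < 1e-3

    def test_identical_frequencies_null(self):
        target = {f"t{i}" for i in range(20)}
        control = {f"c{i}" for i in range(20)}
        spec = {t: {"GO:x"} for t in list(target)[:10] + list(control)[:10]}
        results = go_enrichment(target, control, self._assignments(spec))
        assert all(r.p_raw == pytest.approx(1.0) for r in results)

    def test_planted_category_ranks_first(self):
        """A category at target frequency 0.4 vs control 0.05 dominates the
        ranking in essentially every replicate."""
        wins = 0
        for seed in range(100):
            cfg = SynthConfig(seed=seed, n_target_transcripts=500,
                              n_control_transcripts=500)
            data = generate_domains(cfg)
            accepted = filter_domain_hits(data["hits"])
            assignments = transfer_go(accepted, data["go_map"])
            results = go_enrichment(data["target_ids"], data["control_ids"], assignments)
            if (
                results
                and results[0].category == data["enriched_category"]
                and results[0].p_bonferroni < 1e-6
            ):
                wins += 1
        assert wins >= 99

    def test_adjustment_monotone_and_symmetric(self, small_config):
        data = generate_domains(small_config)
        accepted = filter_domain_hits(data["hits"])
        assignments = transfer_go(accepted, data["go_map"])
        fwd = go_enrichment(data["target_ids"], data["control_ids"], assignments)
        rev = go_enrichment(data["control_ids"], data["target_ids"], assignments)
        by_cat_fwd = {r.category: r for r in fwd}
        by_cat_rev = {r.category: r for r in rev}
        for cat, rf in by_cat_fwd.items():
            rr = by_cat_rev[cat]
            assert rf.p_raw == pytest.approx(rr.p_raw)
            assert rf.count_target == rr.count_control
        raws = [r.p_raw for r in fwd]
        adjs = [r.p_bonferroni for r in fwd]
        order = np.argsort(raws)
        assert all(
            adjs[order[i]] <= adjs[order[i + 1]] + 1e-12 for i in range(len(order) - 1)
        )

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"a"}, {"a", "b"}, [])
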