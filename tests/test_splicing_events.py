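import numpy as np
import pytest
from scipy import stats

from conftest import make_annotation, make_gene, random_gene
from oracles import brute_force_events, events_as_set
from stemtx.splicing_events import (
    classify_frame,
    constitutive_exons,
    detect_events,
    detect_events_annotation,
    frame_bias_test,
    summarize_events,
)


class TestDetectEvents:
    def test_cassette_definition(self):
        gene = make_gene(
            [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]]
        )
        events = detect_events(gene)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "cassette"
        assert ev.core == ((200, 300),)
        assert ev.inclusion_transcripts == {"gX.t1"}
        assert ev.exclusion_transcripts == {"gX.t2"}

    def test_retained_intron_definition(self):
        gene = make_gene([[(0, 300)], [(0, 100), (200, 300)]])
        events = detect_events(gene)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "retained_intron"
        assert ev.core == ((100, 200),)
        # inclusion = the isoform whose mature transcript retains the intron
        assert ev.inclusion_transcripts == {"gX.t1"}

    def test_alt5ss_plus_strand(self):
        gene = make_gene([[(0, 100), (300, 400)], [(0, 150), (300, 400)]])
        events = detect_events(gene)
        assert [e.kind for e in events] == ["alt5ss"]
        assert events[0].core == ((100, 150),)

    def test_alt3ss_plus_strand(self):
        gene = make_gene([[(0, 100), (300, 400)], [(0, 100), (350, 400)]])
        events = detect_events(gene)
        assert [e.kind for e in events] == ["alt3ss"]
        assert events[0].core == ((300, 350),)

    def test_mutually_exclusive(self):
        gene = make_gene(
            [
                [(0, 100), (200, 250), (500, 600)],
                [(0, 100), (300, 350), (500, 600)],
            ]
        )
        events = detect_events(gene)
        assert [e.kind for e in events] == ["mutually_exclusive"]
        assert events[0].core == ((200, 250), (300, 350))

    def test_mxe_not_called_when_skipping_isoform_exists(self):
        """An isoform with neither exon breaks strict mutual exclusivity
        (the structures decay to two cassette events instead)."""
        gene = make_gene(
            [
                [(0, 100), (200, 250), (500, 600)],
                [(0, 100), (300, 350), (500, 600)],
                [(0, 100), (500, 600)],
            ]
        )
        kinds = sorted(e.kind for e in detect_events(gene))
        assert "mutually_exclusive" not in kinds
        assert kinds.count("cassette") == 2

    def test_exon_skipping_not_misread_as_alt_ss(self):
        """The skip junction shares boundaries with flanking introns but the
        intervening segment is intronic, so no alt5ss/alt3ss may fire."""
        gene = make_gene(
            [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]]
        )
        kinds = {e.kind for e in detect_events(gene)}
        assert kinds == {"cassette"}

    def test_single_isoform_gene_has_no_events(self):
        assert detect_events(make_gene([[(0, 100), (200, 300)]])) == []

    def test_matches_bruteforce_oracle_on_random_genes(self):
        rng = np.random.default_rng(20240)
        for i in range(500):
            gene = random_gene(rng, gene_id=f"g{i}")
            assert events_as_set(detect_events(gene)) == brute_force_events(gene), (
                f"disagreement on gene {i}: "
                f"{[(t.transcript_id, [(e.start, e.end) for e in t.exons]) for t in gene.transcripts]}"
            )

    def test_strand_reflection_preserves_alt_ss_classes(self):
        """Mirroring coordinates and flipping strand keeps donor/acceptor
        roles, so each alt splice-site event maps to the same class."""
        rng = np.random.default_rng(99)
        length = 1000
        for i in range(100):
            gene = random_gene(rng, gene_id=f"g{i}")
            reflected = make_gene(
                [
                    [(length - e, length - s) for s, e in reversed(
                        [(x.start, x.end) for x in tx.exons]
                    )]
                    for tx in gene.transcripts
                ],
                strand="-" if gene.strand == "+" else "+",
                gene_id=gene.gene_id,
            )
            fwd = sorted(e.kind for e in detect_events(gene))
            rev = sorted(e.kind for e in detect_events(reflected))
            assert fwd == rev

    def test_planted_events_recovered_exactly_once(self, small_annotation):
        ann, truth = small_annotation
        events = detect_events_annotation(ann)
        planted = truth["events"]
        by_gene_truth = {
            (r.gene_id, r.kind): r for r in planted.itertuples()
        }
        assert len(events) == len(planted)
        for ev in events:
            row = by_gene_truth[(ev.gene_id, ev.kind)]
            cores = sorted(ev.core)
            assert cores[0] == (row.start, row.end)
            if ev.kind == "mutually_exclusive":
                assert cores[1] == (row.start2, row.end2)


class TestFrameClassification:
    @pytest.mark.parametrize(
        "length,phase,in_frame", [(333, 0, True), (29, 2, False), (1, 1, False)]
    )
    def test_phase_examples(self, length, phase, in_frame):
        fc = classify_frame(length)
        assert fc.phase == phase
        assert fc.in_frame is in_frame

    def test_in_frame_codon_count(self):
        assert classify_frame(333).codons == 111
        assert classify_frame(29).codons is None

    def test_phase_periodicity(self):
        for length in range(1, 200):
            assert classify_frame(length).phase == classify_frame(length + 3).phase

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_frame(0)


class TestConstitutiveExons:
    def test_single_isoform_middle_exon(self):
        gene = make_gene([[(0, 10), (20, 30), (40, 50)]])
        cons = constitutive_exons(make_annotation([gene]))
        assert [(e.start, e.end) for e in cons] == [(20, 30)]

    def test_cassette_exon_not_constitutive(self):
        gene = make_gene(
            [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]]
        )
        assert constitutive_exons(make_annotation([gene])) == []

    def test_planted_labels_recovered(self, small_annotation):
        ann, truth = small_annotation
        cons = constitutive_exons(ann)
        got = {(e.transcript_id.rsplit(".", 1)[0], e.start, e.end) for e in cons}
        expected = {
            (r.gene_id, r.start, r.end)
            for r in truth["exon_classes"].itertuples()
            if r.exon_class == "constitutive"
        }
        assert got == expected


class TestFrameBias:
    def test_identical_groups_null(self):
        res = frame_bias_test([3, 4, 5, 6], [3, 4, 5, 6])
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_complete_separation_closed_form(self):
        res = frame_bias_test([3] * 100, [4] * 100)
        assert res["chi2"] == pytest.approx(200.0)
        assert res["p"] < 1e-40

    def test_power_at_study_fractions(self):
        """At the observed in-frame fractions (0.73 cassette vs 0.35
        constitutive) and realistic group sizes the test rejects at
        alpha = 0.001 essentially always."""
        rng = np.random.default_rng(4242)
        rejections = 0
        for _ in range(200):
            cas = np.where(rng.random(512) < 0.73, 3, 4)
            con = np.where(rng.random(5000) < 0.35, 3, 4)
            if frame_bias_test(list(cas), list(con))["p"] < 1e-3:
                rejections += 1
        assert rejections >= 198

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            frame_bias_test([], [3])


class TestEventSummary:
    def test_empty(self):
        s = summarize_events([])
        assert s.total_events == 0 and s.total_genes == 0

    def test_two_events_one_gene(self):
        gene = make_gene(
            [
                [(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)],
                [(0, 10), (40, 50), (80, 90)],
            ]
        )
        events = detect_events(gene)
        s = summarize_events(events)
        assert s.event_counts["cassette"] == 2
        assert s.gene_counts["cassette"] == 1

    def test_planted_counts_recovered(self, small_config, small_annotation):
        ann, _ = small_annotation
        s = summarize_events(detect_events_annotation(ann))
        assert s.event_counts == {
            "cassette": small_config.n_cassette,
            "retained_intron": small_config.n_retained_intron,
            "mutually_exclusive": small_config.n_mutually_exclusive,
            "alt5ss": small_config.n_alt5ss,
            "alt3ss": small_config.n_alt3ss,
        }
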