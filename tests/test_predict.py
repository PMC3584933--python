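import io

import networkx as nx
import pytest

from funclevels.core import HomologyHit, Prediction
from funclevels.dcn import DomainNetwork
from funclevels.predict import (
    PredictionSet,
    finalize,
    predict_dataset,
    predictor1,
    predictor2,
    predictor3,
    read_cafa,
    write_cafa,
)


def psi(subject, evalue, species=None, query="T1"):
    return HomologyHit(query, subject, "psiblast", evalue=evalue, species=species)


def hh(subject, prob, query="T1"):
    return HomologyHit(query, subject, "hhsearch", probability=prob)


ANNOT = {
    "S1": {"GO:0000010", "GO:0000011"},
    "S2": {"GO:0000012"},
    "W1": {"GO:0000013"},
}
DOMAIN_ANNOT = {
    "D1": {"GO:0000020"},
    "D2": {"GO:0000021"},
    "N1": {"GO:0000030"},
    "N2": {"GO:0000030", "GO:0000031"},
}


def star_network():
    g = nx.Graph()
    g.add_edge("D0", "N1")
    g.add_edge("D0", "N2")
    return {"hsapiens": DomainNetwork("hsapiens", g)}


class TestPredictor1:
    def test_strong_homolog_scores_in_level1_band(self):
        preds = predictor1("T1", [psi("S1", 1e-50)], [], [], ANNOT, {}, {})
        assert {p.go_term for p in preds} == {"GO:0000010", "GO:0000011"}
        assert all(0.6 <= p.confidence <= 1.0 and p.level == 1 for p in preds)

    def test_domain_only_target_scores_in_level2_band(self):
        preds = predictor1("T1", [], [hh("D1", 90.0), hh("D2", 70.0)], [],
                           ANNOT, DOMAIN_ANNOT, {})
        assert {p.go_term for p in preds} == {"GO:0000020"}
        assert all(0.54 <= p.confidence <= 0.6 and p.level == 2 for p in preds)

    def test_hard_case_uses_dcn_and_weak_homologs(self):
        fallback = [psi("W1", 0.5, species="hsapiens")]
        preds = predictor1("T1", [psi("S1", 0.5)], [hh("D0", 40.0)], fallback,
                           ANNOT, DOMAIN_ANNOT, star_network())
        by_term = {p.go_term: p for p in preds}
        # weak homolog scored by the floorless level-1 formula
        assert by_term["GO:0000013"].confidence == pytest.approx(
            0.6 + 0.4 * (-__import__("math").log10(0.5)) / 200
        )
        # DCN: N1 and N2 both carry GO:0000030; N2 adds GO:0000031
        assert by_term["GO:0000030"].confidence == pytest.approx(0.3 * 2 / 3)
        assert by_term["GO:0000031"].confidence == pytest.approx(0.3 * 1 / 3)
        assert by_term["GO:0000030"].level == 3

    def test_level_bands_are_nested(self):
        preds = predictor1("T1", [psi("S1", 1e-50)], [hh("D1", 90.0)], [],
                           ANNOT, DOMAIN_ANNOT, {})
        l1 = [p.confidence for p in preds if p.level == 1]
        l2 = [p.confidence for p in preds if p.level == 2]
        assert l1 and l2 and min(l1) >= max(l2)

    def test_no_evidence_gives_empty_entry(self):
        assert predictor1("T1", [], [], [], ANNOT, DOMAIN_ANNOT, {}) == []


class TestPredictor2:
    def test_weighted_frequency_normalised_by_max(self):
        # GO:0000010 seen by 1 psiblast hit (w=4); GO:0000020 by 1 domain (w=2)
        preds = predictor2("T1", [psi("S1", 1e-10)], [hh("D1", 90.0)], [],
                           {"S1": {"GO:0000010"}}, DOMAIN_ANNOT, {})
        confs = {p.go_term: p.confidence for p in preds}
        assert confs["GO:0000010"] == pytest.approx(1.0)
        assert confs["GO:0000020"] == pytest.approx(2 / 4)

    def test_dcn_counts_weighted_once_per_neighbor(self):
        fallback = [psi("W1", 0.5, species="hsapiens")]
        preds = predictor2("T1", [], [hh("D0", 90.0)], fallback,
                           ANNOT, DOMAIN_ANNOT, star_network())
        confs = {p.go_term: p.confidence for p in preds}
        # D0 annotated? no -> only DCN neighbors fire: GO:0000030 w=2*0+1*2=2...
        # D0 carries no annotation, so hhsearch source contributes nothing;
        # neighbor counts: GO:0000030 on 2 domains (w=2), GO:0000031 on 1 (w=1)
        assert confs["GO:0000030"] == pytest.approx(1.0)
        assert confs["GO:0000031"] == pytest.approx(0.5)

    def test_max_term_always_scores_one(self):
        preds = predictor2("T1", [psi("S1", 1e-10), psi("S2", 1e-8)], [], [],
                           ANNOT, {}, {})
        assert preds and max(p.confidence for p in preds) == pytest.approx(1.0)

    def test_empty_sources_fall_back_to_frequency(self):
        fallback = [psi("S1", 5.0), psi("S2", 2.0)]
        preds = predictor2("T1", [], [], fallback, ANNOT, {}, {})
        confs = {p.go_term: p.confidence for p in preds}
        assert confs["GO:0000010"] == pytest.approx(0.5)
        assert confs["GO:0000012"] == pytest.approx(0.5)

    def test_nothing_anywhere_gives_empty(self):
        assert predictor2("T1", [], [], [], ANNOT, {}, {}) == []


class TestPredictor3:
    def test_occurrence_frequency(self):
        hits = [psi("A", 1.0), psi("B", 2.0), psi("C", 3.0), psi("D", 4.0)]
        annot = {"A": {"g"}, "B": {"g"}, "C": {"g"}, "D": {"h"}}
        preds = predictor3("T1", hits, annot)
        confs = {p.go_term: p.confidence for p in preds}
        assert confs["g"] == pytest.approx(0.75)
        assert confs["h"] == pytest.approx(0.25)

    def test_term_on_every_hit_scores_one(self):
        hits = [psi("A", 1.0), psi("B", 2.0)]
        preds = predictor3("T1", hits, {"A": {"g"}, "B": {"g", "h"}})
        confs = {p.go_term: p.confidence for p in preds}
        assert confs["g"] == pytest.approx(1.0)

    def test_unannotated_hits_do_not_dilute(self):
        hits = [psi("A", 1.0), psi("X", 2.0)]
        preds = predictor3("T1", hits, {"A": {"g"}})
        assert preds[0].confidence == pytest.approx(1.0)

    def test_no_hits_gives_empty(self):
        assert predictor3("T1", [], ANNOT) == []


class TestFinalize:
    def test_max_merge(self):
        entry = [Prediction("T", "x", 0.9, 1), Prediction("T", "x", 0.5, 2)]
        out = finalize(entry)
        assert out == [Prediction("T", "x", 0.9, 1)]

    def test_truncation_keeps_highest(self):
        entry = [Prediction("T", f"GO:{i:07d}", (i % 100 + 1) / 100, 1)
                 for i in range(150)]
        out = finalize(entry, max_predictions=100)
        assert len(out) == 100
        dropped_max = max(
            p.confidence for p in finalize(entry, max_predictions=150)[100:]
        )
        assert min(p.confidence for p in out) >= dropped_max

    def test_overconfident_clipped(self):
        out = finalize([Prediction("T", "x", 1.0, 1)] +
                       [Prediction("T", "y", 0.9, 1)])
        assert all(p.confidence <= 1.0 for p in out)

    def test_sort_ties_by_go_id(self):
        entry = [Prediction("T", "GO:0000002", 0.5, 1),
                 Prediction("T", "GO:0000001", 0.5, 1)]
        out = finalize(entry)
        assert [p.go_term for p in out] == ["GO:0000001", "GO:0000002"]


class TestCafaIO:
    def test_format_rule(self):
        ps = PredictionSet({"T1": [Prediction("T1", "GO:0000001", 1.0, 1)]})
        buf = io.StringIO()
        write_cafa(ps, buf)
        assert buf.getvalue() == "T1\tGO:0000001\t1.00\n"

    def test_confidence_floor(self):
        ps = PredictionSet({"T1": [Prediction("T1", "GO:0000001", 0.004, 3)]})
        buf = io.StringIO()
        write_cafa(ps, buf)
        assert buf.getvalue().strip().endswith("0.01")

    def test_empty_set_empty_file(self):
        buf = io.StringIO()
        write_cafa(PredictionSet(), buf)
        assert buf.getvalue() == ""

    def test_duplicate_terms_rejected(self):
        ps = PredictionSet({"T1": [Prediction("T1", "GO:0000001", 0.9, 1),
                                   Prediction("T1", "GO:0000001", 0.5, 2)]})
        with pytest.raises(ValueError, match="duplicate"):
            write_cafa(ps, io.StringIO())

    def test_round_trip(self):
        ps = PredictionSet({
            "T1": [Prediction("T1", "GO:0000001", 0.9, 1),
                   Prediction("T1", "GO:0000002", 0.5, 2)],
            "T2": [Prediction("T2", "GO:0000003", 0.25, 3)],
        })
        buf = io.StringIO()
        write_cafa(ps, buf)
        back = read_cafa(io.StringIO(buf.getvalue()))
        assert back.targets() == ["T1", "T2"]
        assert [p.go_term for p in back["T1"]] == ["GO:0000001", "GO:0000002"]


class TestDeterminismOnWorlds:
    def test_predictors_are_deterministic(self, default_world):
        w = default_world
        args = (
            [h for hs in w.psiblast_hits.values() for h in hs],
            [h for hs in w.hhsearch_hits.values() for h in hs],
            [h for hs in w.fallback_hits.values() for h in hs],
            w.protein_annotations, w.domain_annotations, w.networks,
        )
        for which in (1, 2, 3):
            a = predict_dataset(which, *args)
            b = predict_dataset(which, *args)
            assert a.entries == b.entries

    def test_interval_nesting_across_world(self, default_world):
        w = default_world
        ps = predict_dataset(
            1,
            [h for hs in w.psiblast_hits.values() for h in hs],
            [h for hs in w.hhsearch_hits.values() for h in hs],
            [h for hs in w.fallback_hits.values() for h in hs],
            w.protein_annotations, w.domain_annotations, w.networks,
        )
        for targ in ps.targets():
            if w.strata[targ] == "hard":
                continue  # fallback scores are deliberately outside the bands
            by_level = {}
            for p in ps[targ]:
                by_level.setdefault(p.level, []).append(p.confidence)
            for hi, lo in ((1, 2), (2, 3), (1, 3)):
                if hi in by_level and lo in by_level:
                    assert min(by_level[hi]) >= max(by_level[lo])
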