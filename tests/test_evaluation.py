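import math

import numpy as np
import pytest

from phyloprofiler import (
    ComplexTable,
    MeasureMatrix,
    ReferenceSet,
    build_reference,
    geneset_coverage,
    mmm_hit_rate,
    predict_linkages,
    score_curve,
    simulate_profiles,
    toprank_curve,
    truth_to_reference,
)
from phyloprofiler.evaluation import linkage_confusion


def fs(a, b):
    return frozenset((a, b))


def make_reference(pos_scores, neg_scores):
    """Reference plus score map from two lists of pair scores."""
    positives = {fs(f"p{i}", f"P{i}") for i in range(len(pos_scores))}
    negatives = {fs(f"n{i}", f"N{i}") for i in range(len(neg_scores))}
    ref = ReferenceSet(positives=positives, negatives=negatives, seed=0, ratio=1)
    scores = {fs(f"p{i}", f"P{i}"): s for i, s in enumerate(pos_scores)}
    scores.update({fs(f"n{i}", f"N{i}"): s for i, s in enumerate(neg_scores)})
    return ref, scores


SMALL_TABLE = ComplexTable([
    ("c1", "P1", "mito"), ("c1", "P2", "mito"), ("c1", "P3", "mito"),
    ("c2", "P4", "nucleus"), ("c2", "P5", "nucleus"),
])


class TestBuildReference:
    def test_positives_are_all_intra_complex_pairs(self):
        ref = build_reference(SMALL_TABLE, ratio=1, seed=1)
        assert ref.positives == {fs("P1", "P2"), fs("P1", "P3"),
                                 fs("P2", "P3"), fs("P4", "P5")}

    def test_negative_count_and_seeded_reproducibility(self):
        a = build_reference(SMALL_TABLE, ratio=1, seed=5)
        b = build_reference(SMALL_TABLE, ratio=1, seed=5)
        c = build_reference(SMALL_TABLE, ratio=1, seed=6)
        assert len(a.negatives) == round(1 * len(a.positives)) == 4
        assert a.negatives == b.negatives
        assert a.positives == c.positives
        assert a.negatives != c.negatives  # 4 of 6 candidates: seeds differ

    def test_negatives_cross_complex_only(self):
        ref = build_reference(SMALL_TABLE, ratio=1, seed=2)
        cross = {fs(a, b) for a in ("P1", "P2", "P3") for b in ("P4", "P5")}
        assert ref.negatives <= cross

    def test_shared_localization_blocks_negative_pairs(self):
        table = ComplexTable(SMALL_TABLE.records + [("c3", "P1", "mito"),
                                                    ("c3", "P6", "mito")])
        ref = build_reference(table, ratio=0.5, seed=3)
        # P6's complex shares "mito" with c1, so (P6, c1-member) is ineligible;
        # the only eligible candidates pair a mito protein with a nucleus one
        allowed = {fs(a, b) for a in ("P1", "P2", "P3", "P6")
                   for b in ("P4", "P5")}
        assert ref.negatives and ref.negatives <= allowed

    def test_insufficient_candidates_is_an_error(self):
        with pytest.raises(ValueError, match="eligible negative"):
            build_reference(SMALL_TABLE, ratio=10, seed=1)

    def test_max_subunits_drops_large_complexes(self):
        big = [("c_big", f"B{i}", "er") for i in range(6)]
        table = ComplexTable(SMALL_TABLE.records + big)
        capped = build_reference(table, ratio=0.2, seed=1, max_subunits=5)
        full = build_reference(table, ratio=0.2, seed=1)
        assert len(full.positives) == 4 + 15
        assert len(capped.positives) == 4
        assert not any(p & {f"B{i}" for i in range(6)} for p in capped.positives)


class TestCurves:
    def test_hand_swept_four_pair_roc(self):
        ref, scores = make_reference([0.9, 0.7], [0.8, 0.1])
        curve = score_curve(scores, ref)
        assert curve.auc == pytest.approx(0.75)
        points = list(zip(curve.fpr, curve.tpr))
        assert points == [(0.0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0)]

    def test_perfect_separation(self):
        ref, scores = make_reference([0.9, 0.8, 0.7], [0.3, 0.2, 0.1])
        assert score_curve(scores, ref).auc == pytest.approx(1.0)

    def test_confusion_totals_and_monotonicity(self):
        rng = np.random.default_rng(41)
        ref, scores = make_reference(list(rng.random(30)), list(rng.random(60)))
        curve = score_curve(scores, ref)
        assert ((curve.tp + curve.fn) == 30).all()
        assert ((curve.tn + curve.fp) == 60).all()
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0

    def test_auc_equals_rank_statistic_without_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(43)
        for _ in range(20):
            pos = list(rng.normal(1, 1, size=12))
            neg = list(rng.normal(0, 1, size=25))
            ref, scores = make_reference(pos, neg)
            curve = score_curve(scores, ref)
            # Mann-Whitney two-sample statistic
            u = sum(1 for p in pos for q in neg if p > q)
            assert curve.auc == pytest.approx(u / (12 * 25), abs=1e-9)
            labels = [1] * 12 + [0] * 25
            assert curve.auc == pytest.approx(
                roc_auc_score(labels, pos + neg), abs=1e-9)

    def test_unscored_pairs_count_as_worst(self):
        ref, scores = make_reference([0.9, 0.5], [0.4])
        ref = ReferenceSet(positives=ref.positives,
                           negatives=ref.negatives | {fs("x", "y")},
                           seed=0, ratio=1)
        curve = score_curve(scores, ref)  # (x, y) never scored
        assert curve.auc == pytest.approx(1.0)

    def test_distance_matrices_are_negated(self):
        proteins = ("a", "b", "c")
        dm = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
        matrix = MeasureMatrix(proteins, dm, "lp(2)", "distance")
        ref = ReferenceSet(positives={fs("a", "b")},
                           negatives={fs("a", "c"), fs("b", "c")},
                           seed=0, ratio=2)
        assert score_curve(matrix, ref).auc == pytest.approx(1.0)

    def test_precision_undefined_when_nothing_is_predicted(self,
                                                           four_protein_profile):
        # reference pairs the predictor never selects: TP+FP = 0 at every T,
        # so precision is recorded as NaN rather than 0
        ref = ReferenceSet(positives={fs("A", "C")},
                           negatives={fs("B", "D")}, seed=0, ratio=1)
        curve = toprank_curve(four_protein_profile, ref, t_values=[1])
        assert math.isnan(curve.precision[0])
        assert curve.tp[0] == curve.fp[0] == 0

    def test_empty_reference_rejected(self):
        ref = ReferenceSet(positives=set(), negatives={fs("a", "b")},
                           seed=0, ratio=1)
        with pytest.raises(ValueError):
            score_curve({}, ref)

    def test_toprank_sweep_is_monotone_and_anchored(self):
        profile, truth = simulate_profiles(seed=51, flip_noise=0.1)
        ref, _ = truth_to_reference(truth, ratio=1.0)
        curve = toprank_curve(profile, ref)
        assert curve.sweep == "toprank"
        assert (np.diff(curve.tpr) >= 0).all()
        assert (np.diff(curve.fpr) >= 0).all()
        assert 0.5 < curve.auc <= 1.0
        # per-T confusion agrees with an independent prediction at that T
        for t in (1, 5, 12):
            links = predict_linkages(profile, t)
            tp = len(links.pairs() & ref.positives)
            fp = len(links.pairs() & ref.negatives)
            idx = list(curve.thresholds).index(t)
            assert curve.tp[idx] == tp
            assert curve.fp[idx] == fp


class TestSetMetrics:
    def test_hit_rate_counts_recovered_pairs(self, four_protein_profile):
        links = predict_linkages(four_protein_profile, 1)
        assert mmm_hit_rate(links, [("A", "B"), ("C", "D")]) == 1.0
        assert mmm_hit_rate(links, [("A", "C")]) == 0.0
        assert mmm_hit_rate(
            links, [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                    ("B", "D"), ("C", "D")]) == pytest.approx(2 / 6)
        with pytest.raises(ValueError):
            mmm_hit_rate(links, [])

    def test_geneset_coverage_fractions(self, four_protein_profile):
        links = predict_linkages(four_protein_profile, 1)
        per_set, overall = geneset_coverage(links, {
            "both": {("A", "B"), ("C", "D")},
            "half": {("A", "B"), ("A", "C")},
        })
        assert per_set == {"both": 1.0, "half": 0.5}
        assert overall == pytest.approx(2 / 3)

    def test_seventeen_edge_set_with_fifteen_hits(self):
        # a 17-edge pathway with 15 predicted edges covers 15/17
        edges = {(f"g{i}", f"g{i+1}") for i in range(17)}
        predicted = set(list(edges)[:15])
        links = predict_linkages_like(predicted)
        per_set, _ = geneset_coverage(links, {"pathway": edges})
        assert per_set["pathway"] == pytest.approx(15 / 17)

    def test_linkage_confusion_against_reference(self, four_protein_profile):
        links = predict_linkages(four_protein_profile, 1)
        ref = ReferenceSet(positives={fs("A", "B")},
                           negatives={fs("A", "C")}, seed=0, ratio=1)
        precision, recall = linkage_confusion(links, ref)
        assert precision == 1.0 and recall == 1.0


def predict_linkages_like(pairs):
    """A LinkageSet stand-in carrying just the given pair set."""
    from phyloprofiler import Linkage, LinkageSet

    links = [Linkage(a, b, 1.0, 1.0, 1, False) for a, b in pairs]
    return LinkageSet(links=links, top=1)
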