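"""Evaluation metrics against hand-computed and exhaustive oracles."""

import itertools

import numpy as np
import pytest

from ma_screen.evaluate import (
    CenterDistanceCriterion,
    average_precision,
    count_tolerance_accuracy,
    evaluate_dataset,
    match_detections,
    precision_recall_f1,
    MatchResult,
)
from ma_screen.types import MA, Annotation, CircleDetection, ValidationError

# published per-image microaneurysm counts: (true, classical-detector,
# box-detector) for the ten example images
COUNT_TABLE = [
    (63, 55, 62),
    (27, 32, 27),
    (41, 38, 41),
    (12, 15, 12),
    (8, 11, 8),
    (35, 30, 34),
    (22, 18, 22),
    (17, 20, 17),
    (48, 42, 48),
    (5, 4, 5),
]


def gt(cx, cy, r=3.0):
    return Annotation(MA, cx, cy, r, (cx - r, cy - r, cx + r, cy + r))


def det(cx, cy, score=0.9, r=3):
    return CircleDetection(int(cx), int(cy), r, score)


def oracle_max_matching(dets, gts, criterion):
    """Exhaustive maximum one-to-one matching size on small sets."""
    pairs = [
        (di, gi)
        for di in range(len(dets))
        for gi in range(len(gts))
        if criterion.affinity(dets[di], gts[gi]) is not None
    ]
    best = 0
    for k in range(min(len(dets), len(gts)), 0, -1):
        for combo in itertools.combinations(pairs, k):
            ds = {p[0] for p in combo}
            gs = {p[1] for p in combo}
            if len(ds) == k and len(gs) == k:
                return k
    return best


class TestMatching:
    def test_identity_detections_all_matched(self):
        gts = [gt(10, 10), gt(30, 30), gt(50, 10)]
        dets = [det(10, 10), det(30, 30), det(50, 10)]
        m = match_detections(dets, gts)
        assert (m.true_positives, m.false_positives, m.false_negatives) == (3, 0, 0)

    def test_no_detections_all_false_negatives(self):
        m = match_detections([], [gt(1, 1), gt(9, 9)])
        assert m.false_negatives == 2 and m.true_positives == 0

    def test_two_detections_competing_for_one_gt(self):
        m = match_detections([det(10, 10, 0.9), det(11, 10, 0.8)], [gt(10, 10)])
        assert (m.true_positives, m.false_positives) == (1, 1)

    def test_one_to_one_and_bounded_by_exhaustive_assignment(self):
        rng = np.random.default_rng(10)
        crit = CenterDistanceCriterion()
        for _ in range(20):
            gts = [gt(*rng.uniform(0, 40, 2), r=4.0) for _ in range(int(rng.integers(1, 4)))]
            dets = [
                det(*rng.integers(0, 40, 2), score=float(rng.random()))
                for _ in range(int(rng.integers(0, 4)))
            ]
            m = match_detections(dets, gts, crit)
            assert m.true_positives == len(m.pairs)
            assert len({p[0] for p in m.pairs}) == len(m.pairs)
            assert len({p[1] for p in m.pairs}) == len(m.pairs)
            assert m.true_positives <= oracle_max_matching(dets, gts, crit)
            assert m.true_positives <= min(len(dets), len(gts))


class TestRates:
    def test_arithmetic_example(self):
        p, r, f1 = precision_recall_f1(MatchResult(8, 2, 2))
        assert (p, r, f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_degenerate_zero_conventions(self):
        assert precision_recall_f1(MatchResult(0, 0, 5)) == (0.0, 0.0, 0.0)
        assert precision_recall_f1(MatchResult(0, 0, 0)) == (0.0, 0.0, 0.0)

    def test_random_counts_match_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            tp, fp, fn = (int(v) for v in rng.integers(0, 20, 3))
            p, r, f1 = precision_recall_f1(MatchResult(tp, fp, fn))
            ep = tp / (tp + fp) if tp + fp else 0.0
            er = tp / (tp + fn) if tp + fn else 0.0
            ef = 2 * ep * er / (ep + er) if ep + er else 0.0
            assert (p, r, f1) == (ep, er, ef)
            assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0
            assert f1 <= 2 * min(p, r)  # harmonic-mean bound


class TestCountTolerance:
    def test_published_box_detector_counts_all_within_5_percent(self):
        pairs = [(t, d) for t, _, d in COUNT_TABLE]
        assert count_tolerance_accuracy(pairs, 0.05) == 1.0

    def test_published_classical_counts_all_outside_5_percent(self):
        pairs = [(t, d) for t, d, _ in COUNT_TABLE]
        assert count_tolerance_accuracy(pairs, 0.05) == 0.0

    def test_zero_tolerance_reduces_to_exact_equality(self):
        pairs = [(5, 5), (7, 8), (0, 0), (3, 3)]
        assert count_tolerance_accuracy(pairs, 0.0) == 0.75

    def test_true_zero_passes_only_with_detected_zero(self):
        assert count_tolerance_accuracy([(0, 0)], 0.05) == 1.0
        assert count_tolerance_accuracy([(0, 1)], 0.05) == 0.0

    def test_monotone_in_tolerance(self):
        pairs = [(t, d) for t, d, _ in COUNT_TABLE]
        accs = [count_tolerance_accuracy(pairs, tol) for tol in (0.0, 0.05, 0.1, 0.2, 0.5)]
        assert accs == sorted(accs)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            count_tolerance_accuracy([(-1, 2)])


class TestAveragePrecision:
    def test_perfect_detector_gives_ap_1(self):
        gts = [gt(10, 10), gt(30, 30)]
        dets = [det(10, 10, 0.9), det(30, 30, 0.8)]
        assert average_precision(dets, gts) == 1.0

    def test_all_false_detections_give_ap_0(self):
        gts = [gt(10, 10)]
        dets = [det(100, 100, 0.9), det(200, 200, 0.8)]
        assert average_precision(dets, gts) == 0.0

    def test_no_ground_truth_is_undefined(self):
        assert average_precision([det(1, 1)], []) is None

    def test_matches_hand_computed_pr_staircase(self):
        # 5 detections, 3 ground truths, TP pattern [T, F, T, F, T]:
        # AP = 1/3 * 1 + 1/3 * 2/3 + 1/3 * 3/5 = 34/45
        gts = [gt(0, 0), gt(100, 0), gt(200, 0)]
        dets = [
            det(0, 0, 0.9),       # TP
            det(50, 50, 0.8),     # FP
            det(100, 0, 0.7),     # TP
            det(150, 50, 0.6),    # FP
            det(200, 0, 0.5),     # TP
        ]
        assert average_precision(dets, gts) == pytest.approx(34 / 45)

    def test_invariant_under_monotone_confidence_rescaling(self):
        rng = np.random.default_rng(12)
        gts = [gt(*rng.uniform(0, 100, 2)) for _ in range(5)]
        dets = [
            det(*rng.integers(0, 100, 2), score=float(c))
            for c in np.linspace(0.1, 0.95, 8)
        ]
        base = average_precision(dets, gts)
        rescaled = [
            CircleDetection(d.center_x, d.center_y, d.radius, float(np.sqrt(d.score)))
            for d in dets
        ]
        assert average_precision(rescaled, gts) == pytest.approx(base)


class TestEvaluateDataset:
    def _identity_items(self, n=5):
        rng = np.random.default_rng(13)
        items = []
        for i in range(n):
            gts = [gt(float(x), float(y)) for x, y in rng.integers(10, 90, (4, 2))]
            dets = [det(g.center_x, g.center_y, 0.9) for g in gts]
            items.append((f"img{i}", gts, dets))
        return items

    def test_identity_detector_scores_1_everywhere(self):
        rep = evaluate_dataset(self._identity_items())
        assert rep.sensitivity == rep.precision == rep.f1 == 1.0
        assert rep.count_accuracy == 1.0
        assert rep.mean_average_precision == 1.0

    def test_empty_detector(self):
        items = [("a", [gt(10, 10)], []), ("b", [], [])]
        rep = evaluate_dataset(items)
        assert rep.sensitivity == 0.0
        assert rep.count_accuracy == 0.5  # only the zero-lesion image passes

    def test_deterministic_report(self):
        items = self._identity_items()
        assert evaluate_dataset(items).to_dict() == evaluate_dataset(items).to_dict()

    def test_missing_annotations_listed(self):
        with pytest.raises(ValidationError, match="imgX"):
            evaluate_dataset([("imgX", None, [])])
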