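"""Scoring rules: worked examples per rule, oracles, aggregation, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orbench.answers import serialize_answer
from orbench.baseline import predict_baseline
from orbench.qa import TaskId, generate_for_case
from orbench.scoring import (
    ScoringConfig,
    bootstrap_ci,
    iou_box,
    levenshtein,
    score_benchmark,
    score_bleu1,
    score_box_2d,
    score_label,
    score_people_count,
    score_relative,
    score_scene_graph,
    score_sequence,
    score_set,
)
from orbench.simulate import SimConfig, simulate_corpus


# --- people counting ----------------------------------------------------------

@pytest.mark.parametrize("pred,truth,expected", [(5, 5, 1.0), (4, 5, 0.5), (6, 5, 0.5), (7, 5, 0.0)])
def test_count_rule(pred, truth, expected):
    assert score_people_count(pred, truth) == expected


# --- sets ----------------------------------------------------------------------

def test_set_iou_partial_overlap():
    assert score_set({"surgeon", "nurse"}, {"surgeon", "anesthetist"}) == pytest.approx(1 / 3)


def test_set_identity_disjoint_and_empty():
    assert score_set({"a"}, {"a"}) == 1.0
    assert score_set({"a"}, {"b"}) == 0.0
    assert score_set(set(), set()) == 1.0


# --- labels ---------------------------------------------------------------------

def test_label_match_and_mismatch():
    assert score_label("yes", "yes") == 1.0
    assert score_label("drilling", "sawing") == 0.0
    assert score_label("Yes.", "yes") == 1.0  # normalization


# --- relative error --------------------------------------------------------------

@pytest.mark.parametrize(
    "pred,truth,expected",
    [(2.1, 2.0, 1.0), (2.3, 2.0, 0.5), (3.0, 2.0, 0.0), (2.0, 2.0, 1.0)],
)
def test_relative_error_tiers(pred, truth, expected):
    assert score_relative(pred, truth) == expected


def test_relative_error_zero_truth_convention():
    assert score_relative(0.0, 0.0) == 1.0
    assert score_relative(0.5, 0.0) == 0.0


def test_relative_tiers_strict_at_boundary():
    # exactly 10% error is NOT < 10%
    assert score_relative(2.2, 2.0) == 0.5
    assert score_relative(2.5, 2.0) == 0.0


# --- IoU box --------------------------------------------------------------------

def test_iou_hand_computed():
    assert iou_box((0, 0, 100, 100), (0, 25, 100, 125)) == pytest.approx(7500 / 12500)


def test_iou_identity_disjoint_symmetric():
    assert iou_box((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
    assert iou_box((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0
    a, b = (0, 0, 50, 80), (10, 20, 70, 60)
    assert iou_box(a, b) == pytest.approx(iou_box(b, a))


def test_iou_degenerate_boxes():
    assert iou_box((5, 5, 5, 5), (0, 0, 10, 10)) == 0.0
    assert iou_box((5, 5, 5, 5), (5, 5, 5, 5)) == 1.0


@pytest.mark.parametrize(
    "pred,truth,expected",
    [
        ((0, 0, 100, 100), (0, 0, 100, 100), 1.0),   # IoU 1
        ((0, 25, 100, 125), (0, 0, 100, 100), 0.75), # IoU 0.6
        ((0, 70, 100, 170), (0, 0, 100, 100), 0.25), # IoU 3000/17000 ~ 0.176
        ((0, 95, 100, 195), (0, 0, 100, 100), 0.0),  # IoU ~ 0.026
    ],
)
def test_2d_tiers(pred, truth, expected):
    assert score_box_2d(pred, truth) == expected


def test_2d_tier_thresholds_inclusive():
    # construct IoU exactly 0.5: boxes (0,0,100,100) vs (0,0,100,50) unioned
    assert iou_box((0, 0, 100, 50), (0, 0, 100, 100)) == pytest.approx(0.5)
    assert score_box_2d((0, 0, 100, 50), (0, 0, 100, 100)) == 0.75


# --- scene graphs -----------------------------------------------------------------

def test_macro_f1_worked_example():
    truth = [("s", "holding", "drill"), ("n", "assisting", "s")]
    pred = [("s", "holding", "drill"), ("s", "cutting", "p")]
    # per-class F1: holding 1, assisting 0, cutting 0 -> macro 1/3
    assert score_scene_graph(pred, truth) == pytest.approx(1 / 3)


def test_macro_f1_identity_and_empty_pred():
    t = [("a", "p", "b"), ("c", "q", "d")]
    assert score_scene_graph(t, t) == 1.0
    assert score_scene_graph([], t) == 0.0


# --- sequences --------------------------------------------------------------------

def test_sequence_worked_example():
    pred = ["surgeon", "table", "nurse"]
    truth = ["table", "surgeon", "nurse"]
    assert score_sequence(pred, truth) == pytest.approx(1 / 3)


def test_sequence_identity_and_empty():
    assert score_sequence(["a", "b"], ["a", "b"]) == 1.0
    assert score_sequence([], []) == 1.0


def _dp_oracle(a, b):
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
                D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return D[n][m]


def test_levenshtein_matches_dp_oracle_on_1000_random_pairs():
    rng = np.random.default_rng(42)
    vocab = [f"w{i}" for i in range(6)]
    for _ in range(1000):
        a = [vocab[i] for i in rng.integers(0, 6, size=rng.integers(0, 9))]
        b = [vocab[i] for i in rng.integers(0, 6, size=rng.integers(0, 9))]
        assert levenshtein(a, b) == _dp_oracle(a, b)


# --- BLEU-1 ------------------------------------------------------------------------

def test_bleu1_identity():
    assert score_bleu1("heart rate 72 bpm", "heart rate 72 bpm") == pytest.approx(1.0)


def test_bleu1_brevity_penalty_worked_example():
    # precision 1, brevity penalty exp(1 - 4/3) = 0.7165
    s = score_bleu1("heart rate 72", "heart rate 72 bpm")
    assert s == pytest.approx(math.exp(1 - 4 / 3), abs=1e-3)
    assert s == pytest.approx(0.717, abs=1e-3)


def test_bleu1_zero_overlap_and_empty():
    assert score_bleu1("abc def", "xyz uvw") == 0.0
    assert score_bleu1("", "something") == 0.0


def test_bleu1_clipping():
    # "a a a a" vs "a b": clipped count 1, precision 1/4, c>r so BP=1
    assert score_bleu1("a a a a", "a b") == pytest.approx(0.25)


# --- tier monotonicity property ------------------------------------------------------

@given(st.floats(0, 1), st.floats(0, 1))
@settings(max_examples=200, deadline=None)
def test_tier_functions_monotone(u, v):
    lo, hi = sorted((u, v))
    # higher IoU never scores lower
    t = (0, 0, 100, 100)

    def box_with_iou(q):
        # equal-size boxes offset vertically by d: IoU = (100-d)/(100+d)
        off = 100 * (1 - q) / (1 + q)
        return (0, off, 100, 100 + off)

    assert score_box_2d(box_with_iou(hi), t) >= score_box_2d(box_with_iou(lo), t)
    # smaller relative error never scores lower
    assert score_relative(1 + lo, 1.0) >= score_relative(1 + hi, 1.0)


# --- aggregation ----------------------------------------------------------------------

def _tiny_benchmark():
    cfg = SimConfig(n_cases_per_source=1, timepoints_per_case=6, seed=3)
    corpus = simulate_corpus(cfg)
    bench = []
    for tl in corpus:
        for qa in generate_for_case(tl):
            qa.split = "test"
            bench.append(qa)
    return bench


def test_perfect_prediction_fixed_point_every_task():
    """Scoring serialized ground truth against itself yields 1.0 for all 23 tasks."""
    bench = _tiny_benchmark()
    assert {qa.task for qa in bench} == set(TaskId)
    preds = {qa.qa_id: serialize_answer(qa.answer) for qa in bench}
    report = score_benchmark(bench, preds, seed=0)
    assert report.overall.mean == pytest.approx(1.0)
    for task, cell in report.per_task.items():
        assert cell.mean == pytest.approx(1.0), task
    assert report.parse_failure_rate == 0.0


def test_missing_predictions_scored_zero_and_counted():
    bench = _tiny_benchmark()[:10]
    preds = {qa.qa_id: serialize_answer(qa.answer) for qa in bench[:5]}
    report = score_benchmark(bench, preds, seed=0)
    assert report.n_missing == 5
    assert report.overall.mean == pytest.approx(0.5)


def test_report_means_equal_hand_average():
    bench = _tiny_benchmark()
    by_task = {}
    for qa in bench:
        by_task.setdefault(qa.task, []).append(qa)
    # pick 6 people-counting items, predict: 3 exact, 2 off-by-one, 1 far off
    items = by_task[TaskId.PEOPLE_COUNTING][:6]
    assert len(items) == 6
    preds = {}
    for i, qa in enumerate(items):
        truth = qa.answer.value
        pred = truth if i < 3 else (truth + 1 if i < 5 else truth + 4)
        preds[qa.qa_id] = str(pred)
    report = score_benchmark(items, preds, seed=0)
    assert report.overall.mean == pytest.approx((3 * 1.0 + 2 * 0.5 + 0.0) / 6)
    assert report.overall.n == 6


def test_scores_always_in_unit_interval(small_pool):
    bench = [qa for qa in small_pool[::11]]
    preds = {qa.qa_id: "garbled 7 output, maybe (a, b, c)" for qa in bench}
    report = score_benchmark(bench, preds, seed=1)
    assert all(0.0 <= s <= 1.0 for s in report.item_scores.values())
    assert 0.0 <= report.overall.mean <= 1.0


# --- bootstrap -------------------------------------------------------------------------

def test_bootstrap_constant_scores_zero_width():
    lo, hi = bootstrap_ci([0.7] * 50, seed=1)
    assert lo == hi == pytest.approx(0.7)


def test_bootstrap_deterministic_under_seed():
    scores = list(np.random.default_rng(0).random(100))
    assert bootstrap_ci(scores, seed=5) == bootstrap_ci(scores, seed=5)


def test_bootstrap_brackets_mean():
    scores = list(np.random.default_rng(3).random(40))
    lo, hi = bootstrap_ci(scores, seed=2)
    m = float(np.mean(scores))
    assert lo <= m <= hi


def test_bootstrap_single_item_degenerate_with_warning():
    with pytest.warns(UserWarning):
        lo, hi = bootstrap_ci([0.4], seed=0)
    assert lo == hi == pytest.approx(0.4)


def test_bootstrap_matches_binomial_oracle():
    """Bernoulli(0.5) scores, n=1000: bootstrap CI of the mean should match a
    direct binomial simulation of resampled means."""
    rng = np.random.default_rng(11)
    scores = (rng.random(1000) < 0.5).astype(float)
    p_hat = scores.mean()
    lo, hi = bootstrap_ci(list(scores), resamples=2000, seed=4)
    # direct oracle: resampled mean ~ Binomial(n, p_hat)/n
    sims = rng.binomial(1000, p_hat, size=20000) / 1000
    olo, ohi = np.quantile(sims, [0.025, 0.975])
    assert lo == pytest.approx(olo, abs=0.01)
    assert hi == pytest.approx(ohi, abs=0.01)
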