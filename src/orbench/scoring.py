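"""Composite benchmark scoring: per-task rules, aggregation, bootstrap CIs.

Every task maps to exactly one 0-1 rule:

* people counting — 1.0 exact, 0.5 off by one, 0.0 otherwise;
* set tasks (roles, tools, entities) — set intersection over union;
* single-label and binary tasks — exact match after normalization;
* relative-error tasks (3D distance, progress, time-until) — 1.0 for
  relative error < 10%, 0.5 for < 25%, 0.0 beyond (strict inequalities);
* 2D localization — tiered box IoU: 1.0 at IoU >= 0.75, 0.75 at >= 0.5,
  0.5 at >= 0.25, 0.25 at >= 0.125 (inclusive thresholds);
* scene-graph generation — macro F1 over predicate classes of exact
  triplet matches;
* sorted entity detection — 1 minus normalized token-level Levenshtein
  distance;
* monitor text — BLEU-1 (clipped unigram precision x brevity penalty).

3D localization and gaze location have no printed rule; this package reuses
the relative-error tiers on Euclidean error normalized by the room (resp.
image) diagonal — see docs/methods.md.

Aggregation: mean per task, per source dataset, and overall (micro over
items; the per-task macro mean is also reported), each with a 95% percentile
bootstrap confidence interval over test items (1,000 resamples).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .answers import AnswerValue, normalize_token, parse_answer
from .qa import QAPair, TaskId, TASK_ANSWER_KIND

# ---------------------------------------------------------------------------
# config

@dataclass(frozen=True)
class ScoringConfig:
    count_off_by_one: float = 0.5
    relative_tiers: Tuple[Tuple[float, float], ...] = ((0.10, 1.0), (0.25, 0.5))
    iou_tiers: Tuple[Tuple[float, float], ...] = ((0.75, 1.0), (0.5, 0.75), (0.25, 0.5), (0.125, 0.25))
    bootstrap_resamples: int = 1000
    bootstrap_level: float = 0.95
    room_extent: Tuple[float, float, float] = (10.0, 6.0, 3.0)
    image_size: Tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        rel = [t for t, _ in self.relative_tiers]
        iou = [t for t, _ in self.iou_tiers]
        if sorted(rel) != rel or sorted(iou, reverse=True) != iou:
            raise ValueError("tier thresholds must be ordered")

    @property
    def room_diagonal(self) -> float:
        return math.sqrt(sum(e * e for e in self.room_extent))

    @property
    def image_diagonal(self) -> float:
        return math.hypot(*self.image_size)


@dataclass
class PredictionRecord:
    qa_id: str
    raw_text: str
    parsed: Optional[AnswerValue] = None


# ---------------------------------------------------------------------------
# per-task rules

def score_people_count(pred: int, truth: int) -> float:
    """1.0 exact, 0.5 off by one, 0.0 otherwise."""
    d = abs(int(pred) - int(truth))
    return 1.0 if d == 0 else (0.5 if d == 1 else 0.0)


def score_set(pred: Iterable[str], truth: Iterable[str]) -> float:
    """Set IoU after token normalization; two empty sets agree perfectly."""
    p = {normalize_token(x) for x in pred}
    t = {normalize_token(x) for x in truth}
    if not p and not t:
        return 1.0
    return len(p & t) / len(p | t)


def score_label(pred: str, truth: str) -> float:
    return 1.0 if normalize_token(pred) == normalize_token(truth) else 0.0


def score_relative(pred: float, truth: float, tiers=((0.10, 1.0), (0.25, 0.5))) -> float:
    """Tiered relative error, strict inequalities: <10% -> 1.0, <25% -> 0.5."""
    if truth == 0:
        return 1.0 if pred == 0 else 0.0
    err = abs(pred - truth) / abs(truth)
    for thresh, score in tiers:
        if err < thresh:
            return score
    return 0.0


def iou_box(a: Sequence[float], b: Sequence[float]) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(0.0, ax2 - ax1) * max(0.0, ay2 - ay1)
    area_b = max(0.0, bx2 - bx1) * max(0.0, by2 - by1)
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = area_a + area_b - inter
    if union <= 0.0:
        # both degenerate: equal boxes count as a match
        return 1.0 if tuple(a) == tuple(b) and area_a == 0.0 else 0.0
    return inter / union


def score_box_2d(
    pred: Sequence[float], truth: Sequence[float],
    tiers=((0.75, 1.0), (0.5, 0.75), (0.25, 0.5), (0.125, 0.25)),
) -> float:
    """Tiered IoU with inclusive thresholds."""
    iou = iou_box(pred, truth)
    for thresh, score in tiers:
        if iou >= thresh:
            return score
    return 0.0


def score_scene_graph(
    pred: Iterable[Tuple[str, str, str]], truth: Iterable[Tuple[str, str, str]]
) -> float:
    """Macro F1 over the predicate classes occurring in truth or prediction;
    matches are exact normalized triplets."""
    norm = lambda t: tuple(normalize_token(x) for x in t)
    p = {norm(t) for t in pred}
    t = {norm(x) for x in truth}
    classes = {x[1] for x in p} | {x[1] for x in t}
    if not classes:
        return 1.0
    f1s = []
    for c in sorted(classes):
        pc = {x for x in p if x[1] == c}
        tc = {x for x in t if x[1] == c}
        tp = len(pc & tc)
        prec = tp / len(pc) if pc else 0.0
        rec = tp / len(tc) if tc else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return float(np.mean(f1s))


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Token-level edit distance (insert/delete/substitute, unit costs)."""
    n, m = len(a), len(b)
    if n == 0:
        return m
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def score_sequence(pred: Sequence[str], truth: Sequence[str]) -> float:
    """1 - normalized token Levenshtein distance; two empty sequences -> 1.0."""
    p = [normalize_token(x) for x in pred]
    t = [normalize_token(x) for x in truth]
    denom = max(len(p), len(t))
    if denom == 0:
        return 1.0
    return 1.0 - levenshtein(p, t) / denom


def score_bleu1(pred: str, truth: str) -> float:
    """BLEU-1: clipped unigram precision x brevity penalty exp(min(0, 1-r/c))."""
    p_toks = pred.casefold().split()
    t_toks = truth.casefold().split()
    if not p_toks:
        return 0.0
    p_counts, t_counts = Counter(p_toks), Counter(t_toks)
    clipped = sum(min(c, t_counts[w]) for w, c in p_counts.items())
    precision = clipped / len(p_toks)
    bp = math.exp(min(0.0, 1.0 - len(t_toks) / len(p_toks)))
    return precision * bp


def _score_point(pred: Sequence[float], truth: Sequence[float], diagonal: float, tiers) -> float:
    err = math.sqrt(sum((float(a) - float(b)) ** 2 for a, b in zip(pred, truth)))
    rel = err / diagonal
    for thresh, score in tiers:
        if rel < thresh:
            return score
    return 0.0


# ---------------------------------------------------------------------------
# dispatch

_COUNT_TASKS = {TaskId.PEOPLE_COUNTING}
_SET_TASKS = {TaskId.ROLE_DETECTION, TaskId.TOOL_DETECTION, TaskId.ENTITY_DETECTION}
_LABEL_TASKS = {
    TaskId.INTERACTION_DETECTION, TaskId.ATTRIBUTE_DETECTION, TaskId.ACTION_DETECTION,
    TaskId.ROBOT_STEP_DETECTION, TaskId.NEXT_ROBOT_STEP_ESTIMATION, TaskId.GAZE_OBJECT_DETECTION,
    TaskId.IS_COMPLETED, TaskId.IS_BASE_ARRAY_VISIBLE, TaskId.IS_ROBOT_CALIBRATED,
    TaskId.STERILITY_BREACH_DETECTION,
}
_RELATIVE_TASKS = {TaskId.DISTANCE_3D, TaskId.ESTIMATE_STATUS, TaskId.ESTIMATE_TIME_UNTIL}


def score_item(
    truth: AnswerValue, pred: Optional[AnswerValue], task: TaskId,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Score a parsed prediction against the ground truth for one QA item.

    A missing or unparseable prediction scores 0.0 (conservative).
    """
    if pred is None:
        return 0.0
    if task in _COUNT_TASKS:
        return score_people_count(pred.value, truth.value)
    if task in _SET_TASKS:
        return score_set(pred.value, truth.value)
    if task in _LABEL_TASKS:
        return score_label(str(pred.value), str(truth.value))
    if task in _RELATIVE_TASKS:
        return score_relative(float(pred.value), float(truth.value), config.relative_tiers)
    if task is TaskId.LOCALIZATION_2D:
        return score_box_2d(pred.value, truth.value, config.iou_tiers)
    if task is TaskId.LOCALIZATION_3D:
        return _score_point(pred.value, truth.value, config.room_diagonal, config.relative_tiers)
    if task is TaskId.GAZE_LOCATION:
        return _score_point(pred.value, truth.value, config.image_diagonal, config.relative_tiers)
    if task is TaskId.SCENE_GRAPH_GENERATION:
        return score_scene_graph(pred.value, truth.value)
    if task is TaskId.SORTED_ENTITY_DETECTION:
        return score_sequence(pred.value, truth.value)
    if task is TaskId.MONITOR_TEXT_RECOGNITION:
        return score_bleu1(str(pred.value), str(truth.value))
    raise ValueError(f"no scoring rule for task {task}")


assert all(
    t in _COUNT_TASKS | _SET_TASKS | _LABEL_TASKS | _RELATIVE_TASKS
    or t in (
        TaskId.LOCALIZATION_2D, TaskId.LOCALIZATION_3D, TaskId.GAZE_LOCATION,
        TaskId.SCENE_GRAPH_GENERATION, TaskId.SORTED_ENTITY_DETECTION,
        TaskId.MONITOR_TEXT_RECOGNITION,
    )
    for t in TaskId
), "every task must map to exactly one rule"


# ---------------------------------------------------------------------------
# aggregation and bootstrap

def bootstrap_ci(
    item_scores: Sequence[float],
    resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap interval of the mean; degenerate (mean, mean) at n<2."""
    scores = np.asarray(item_scores, dtype=float)
    mean = float(scores.mean()) if scores.size else float("nan")
    if scores.size < 2:
        import warnings

        warnings.warn("bootstrap_ci with n<2 items: degenerate interval")
        return (mean, mean)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(resamples, scores.size))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return (min(float(lo), mean), max(float(hi), mean))


@dataclass
class Cell:
    mean: float
    lo: float
    hi: float
    n: int

    def to_json(self) -> dict:
        return {"mean": self.mean, "ci95": [self.lo, self.hi], "n": self.n}


@dataclass
class ScoreReport:
    overall: Cell
    per_task: Dict[str, Cell]
    per_dataset: Dict[str, Cell]
    macro_task_mean: float
    parse_failure_rate: float
    n_missing: int
    item_scores: Dict[str, float] = field(default_factory=dict, repr=False)

    def to_json(self) -> dict:
        return {
            "overall": self.overall.to_json(),
            "per_task": {k: v.to_json() for k, v in self.per_task.items()},
            "per_dataset": {k: v.to_json() for k, v in self.per_dataset.items()},
            "macro_task_mean": self.macro_task_mean,
            "parse_failure_rate": self.parse_failure_rate,
            "n_missing": self.n_missing,
        }

    def to_text(self) -> str:
        lines = [
            f"overall score: {self.overall.mean:.3f} "
            f"(95% CI [{self.overall.lo:.3f}, {self.overall.hi:.3f}], n={self.overall.n})",
            f"macro task mean: {self.macro_task_mean:.3f}",
            f"parse failures: {self.parse_failure_rate:.1%}; missing predictions: {self.n_missing}",
            "per task:",
        ]
        for k in sorted(self.per_task):
            c = self.per_task[k]
            lines.append(f"  {k:<28} {c.mean:.3f} [{c.lo:.3f}, {c.hi:.3f}] n={c.n}")
        lines.append("per dataset:")
        for k in sorted(self.per_dataset):
            c = self.per_dataset[k]
            lines.append(f"  {k:<28} {c.mean:.3f} [{c.lo:.3f}, {c.hi:.3f}] n={c.n}")
        return "\n".join(lines)


def parse_prediction(raw_text: str, task: TaskId) -> Optional[AnswerValue]:
    tag, units = TASK_ANSWER_KIND[task]
    if tag == "binary":
        return parse_answer(raw_text, "binary")
    return parse_answer(raw_text, tag, units)


def score_benchmark(
    benchmark: Sequence[QAPair],
    predictions: Dict[str, str],
    config: ScoringConfig = ScoringConfig(),
    seed: int = 0,
) -> ScoreReport:
    """Score raw-text predictions (keyed by qa_id) against a benchmark.

    Missing predictions score 0.0 and are counted; aggregation is the item
    mean overall (micro), per task and per source dataset, each with a 95%
    percentile bootstrap CI (1,000 resamples).
    """
    item_scores: Dict[str, float] = {}
    by_task: Dict[str, List[float]] = defaultdict(list)
    by_source: Dict[str, List[float]] = defaultdict(list)
    n_missing = 0
    n_failures = 0
    for qa in benchmark:
        raw = predictions.get(qa.qa_id)
        if raw is None:
            n_missing += 1
            s = 0.0
        else:
            parsed = parse_prediction(raw, qa.task)
            if parsed is None:
                n_failures += 1
            s = score_item(qa.answer, parsed, qa.task, config)
        item_scores[qa.qa_id] = s
        by_task[qa.task.value].append(s)
        by_source[qa.source_tag].append(s)

    def cell(scores: List[float], salt: int) -> Cell:
        lo, hi = bootstrap_ci(scores, config.bootstrap_resamples, config.bootstrap_level, seed + salt)
        return Cell(float(np.mean(scores)), lo, hi, len(scores))

    all_scores = list(item_scores.values())
    per_task = {k: cell(v, i + 1) for i, (k, v) in enumerate(sorted(by_task.items()))}
    per_dataset = {k: cell(v, 1000 + i) for i, (k, v) in enumerate(sorted(by_source.items()))}
    n_pred = len(benchmark) - n_missing
    return ScoreReport(
        overall=cell(all_scores, 0),
        per_task=per_task,
        per_dataset=per_dataset,
        macro_task_mean=float(np.mean([c.mean for c in per_task.values()])) if per_task else float("nan"),
        parse_failure_rate=n_failures / n_pred if n_pred else 0.0,
        n_missing=n_missing,
        item_scores=item_scores,
    )
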