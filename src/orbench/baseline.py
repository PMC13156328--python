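"""Statistical baseline: always predict each task's most frequent answer.

The baseline stores one constant per task fitted on the training pool — the
modal answer for categorical, set, sequence, triplet and text tasks ("no" for
binary predicates when that is the mode), the arithmetic mean for scalar tasks
(e.g. the average 3D distance), and the coordinate-wise mean for boxes and
points. It is the reference floor any learned system must clear.

A uniform-random guesser (one draw from the task's observed training answers
per question) is also provided as an even weaker comparison point.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .answers import AnswerValue, serialize_answer
from .qa import QAPair, TaskId, TASK_ANSWER_KIND

_MEAN_TAGS = {"scalar"}
_COORD_TAGS = {"box", "point2", "point3"}


@dataclass
class BaselineModel:
    """Per-task constant prediction, as canonical answer text."""

    constants: Dict[TaskId, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {t.value: v for t, v in self.constants.items()}

    @staticmethod
    def from_json(d: dict) -> "BaselineModel":
        return BaselineModel({TaskId(k): v for k, v in d.items()})


def fit_baseline(train_pool: Sequence[QAPair]) -> BaselineModel:
    """Fit the most-frequent-answer constant per task.

    Categorical-family tasks take the modal serialized answer (ties broken
    lexicographically); scalar tasks the mean; box/point tasks the
    coordinate-wise mean. Tasks absent from the pool are omitted with a
    warning.
    """
    by_task: Dict[TaskId, List[AnswerValue]] = defaultdict(list)
    for qa in train_pool:
        by_task[qa.task].append(qa.answer)

    model = BaselineModel()
    for task in TaskId:
        answers = by_task.get(task)
        if not answers:
            continue
        tag, units = TASK_ANSWER_KIND[task]
        if tag in _MEAN_TAGS:
            mean = float(np.mean([a.value for a in answers]))
            model.constants[task] = serialize_answer(AnswerValue("scalar", round(mean, 2), units))
        elif tag in _COORD_TAGS:
            coords = np.mean([a.value for a in answers], axis=0)
            if tag == "point3":
                value = tuple(round(float(c), 2) for c in coords)
            else:
                value = tuple(int(round(float(c))) for c in coords)
            model.constants[task] = serialize_answer(AnswerValue(tag, value))
        else:
            counts = Counter(serialize_answer(a) for a in answers)
            top = max(counts.values())  # ties -> lexicographically smallest

            model.constants[task] = min(k for k, v in counts.items() if v == top)
    import warnings

    for task in TaskId:
        if task not in model.constants:
            warnings.warn(f"task {task.value} absent from training pool; omitted from baseline")
    return model


def predict_baseline(model: BaselineModel, benchmark: Sequence[QAPair]) -> Dict[str, str]:
    """One constant prediction per QA; tasks missing from the model yield an
    empty prediction (which the scorer counts as 0)."""
    return {
        qa.qa_id: model.constants[qa.task]
        for qa in benchmark
        if qa.task in model.constants
    }


def predict_random(
    train_pool: Sequence[QAPair], benchmark: Sequence[QAPair], seed: int = 0
) -> Dict[str, str]:
    """Uniform-random guesser: each question gets an answer drawn uniformly
    from the training pool's observed answers for that task."""
    rng = np.random.default_rng(seed)
    by_task: Dict[TaskId, List[str]] = defaultdict(list)
    for qa in train_pool:
        by_task[qa.task].append(serialize_answer(qa.answer))
    out: Dict[str, str] = {}
    for qa in benchmark:
        choices = by_task.get(qa.task)
        if choices:
            out[qa.qa_id] = choices[int(rng.integers(len(choices)))]
    return out
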