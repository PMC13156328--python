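"""Diversity-aware benchmark sampling.

A large generated QA pool is reduced to a benchmark by stratified, weighted
sampling without replacement: first by split (train/val/test — never crossed),
then by source with fixed mixing proportions (defaults 0.40 MM-OR-like /
0.30 EgoSurgery-like / 0.20 4D-OR-like / 0.10 MVOR-like), then by task with
equal quotas within a source, and finally weighted by inverse question-template
and inverse answer-bin frequency so long-tail answers are prioritized over the
modal ones.

Weighted sampling without replacement uses exponential-sort keys
(Efraimidis–Spirakis): item i gets key u_i^(1/w_i) with u_i ~ U(0,1); the
top-k keys form the sample. Items are keyed in qa_id order, so the draw is
deterministic under a seed and independent of pool ordering.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .answers import AnswerValue, serialize_answer
from .qa import QAPair, TaskId

DEFAULT_DATASET_WEIGHTS = {
    "mmor-like": 0.40,
    "egosurgery-like": 0.30,
    "4dor-like": 0.20,
    "mvor-like": 0.10,
}


@dataclass(frozen=True)
class BinningSpec:
    """How continuous answers are discretized to define 'answer frequency'."""

    scalar_widths: Tuple[Tuple[str, float], ...] = (("m", 0.25), ("s", 10.0), ("%", 10.0))
    image_grid: int = 8
    image_size: Tuple[int, int] = (640, 480)
    space_cell_m: float = 0.5

    def scalar_width(self, units: str) -> float:
        for u, w in self.scalar_widths:
            if u == units:
                return w
        return 1.0


@dataclass(frozen=True)
class SamplerConfig:
    dataset_weights: Optional[Dict[str, float]] = None
    target_sizes: Optional[Dict[str, int]] = None
    binning: BinningSpec = BinningSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.weights
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("dataset_weights must sum to 1")
        if any(n < 1 for n in self.sizes.values()):
            raise ValueError("target sizes must be >= 1")

    @property
    def weights(self) -> Dict[str, float]:
        return self.dataset_weights or dict(DEFAULT_DATASET_WEIGHTS)

    @property
    def sizes(self) -> Dict[str, int]:
        return self.target_sizes or {"train": 1_000_000, "val": 10_000, "test": 10_000}


def bin_answer(answer: AnswerValue, spec: BinningSpec = BinningSpec()) -> str:
    """Bin key for an answer: categorical answers bin to themselves, scalars by
    fixed width, boxes and points by image-grid (or room-grid) cell."""
    t, v = answer.tag, answer.value
    if t in ("count", "label", "binary", "text"):
        return f"{t}:{v}"
    if t == "set":
        return "set:" + ",".join(sorted(v))
    if t == "sequence":
        return "seq:" + ",".join(v)
    if t == "triplets":
        return "tri:" + ";".join(",".join(x) for x in sorted(v))
    if t == "scalar":
        w = spec.scalar_width(answer.units or "")
        return f"scalar:{answer.units}:{int(math.floor(float(v) / w))}"
    if t in ("box", "point2"):
        if t == "box":
            cx, cy = (v[0] + v[2]) / 2.0, (v[1] + v[3]) / 2.0
        else:
            cx, cy = float(v[0]), float(v[1])
        gw = spec.image_size[0] / spec.image_grid
        gh = spec.image_size[1] / spec.image_grid
        return f"{t}:{int(cx // gw)},{int(cy // gh)}"
    if t == "point3":
        c = spec.space_cell_m
        return "p3:" + ",".join(str(int(math.floor(x / c))) for x in v)
    raise ValueError(f"unknown tag {t}")


@dataclass
class FrequencyTable:
    """Question-template and answer-bin counts over a pool."""

    question_counts: Counter = field(default_factory=Counter)
    answer_counts: Counter = field(default_factory=Counter)
    spec: BinningSpec = BinningSpec()

    @staticmethod
    def fit(pool: Sequence[QAPair], spec: BinningSpec = BinningSpec()) -> "FrequencyTable":
        ft = FrequencyTable(spec=spec)
        for qa in pool:
            ft.question_counts[(qa.task, qa.template_id)] += 1
            ft.answer_counts[(qa.task, bin_answer(qa.answer, spec))] += 1
        return ft


def sampling_weight(qa: QAPair, freq: FrequencyTable) -> float:
    """Weight proportional to 1 / (question count x answer-bin count)."""
    qk = (qa.task, qa.template_id)
    ak = (qa.task, bin_answer(qa.answer, freq.spec))
    qc, ac = freq.question_counts.get(qk, 0), freq.answer_counts.get(ak, 0)
    if qc < 1 or ac < 1:
        raise KeyError(f"pool/table mismatch for {qa.qa_id}: unseen key")
    return 1.0 / (qc * ac)


@dataclass
class BenchmarkSplit:
    """Sampled benchmark: QA pairs per split plus per-stratum bookkeeping."""

    splits: Dict[str, List[QAPair]]
    stratum_counts: Dict[Tuple[str, str, str], int]
    shortfalls: Dict[Tuple[str, str, str], int]

    def all_pairs(self) -> List[QAPair]:
        return [qa for split in self.splits.values() for qa in split]


def _largest_remainder(total: int, props: Sequence[float]) -> List[int]:
    exact = [p * total for p in props]
    counts = [int(math.floor(e)) for e in exact]
    rem = total - sum(counts)
    order = sorted(range(len(props)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _weighted_sample_wor(
    items: List[QAPair], weights: List[float], k: int, rng: np.random.Generator
) -> List[QAPair]:
    if k >= len(items):
        return list(items)
    u = rng.random(len(items))
    keys = u ** (1.0 / np.asarray(weights))
    top = np.argpartition(-keys, k)[:k]
    return [items[i] for i in top]


def sample_benchmark(
    pool: Sequence[QAPair], config: SamplerConfig, seed: Optional[int] = None
) -> BenchmarkSplit:
    """Stratified diversity sampling of a labeled pool into a benchmark.

    Every pool item must carry a split label (from case-level split
    assignment); sampling never crosses split boundaries. Exhausted strata
    contribute everything they have and are recorded as shortfalls.
    """
    seed = config.seed if seed is None else seed
    if any(qa.split is None for qa in pool):
        raise ValueError("pool items must carry split labels")
    freq = FrequencyTable.fit(pool, config.binning)
    weights_cfg = config.weights

    by_stratum: Dict[Tuple[str, str, TaskId], List[QAPair]] = {}
    for qa in pool:
        by_stratum.setdefault((qa.split, qa.source_tag, qa.task), []).append(qa)

    splits: Dict[str, List[QAPair]] = {}
    stratum_counts: Dict[Tuple[str, str, str], int] = {}
    shortfalls: Dict[Tuple[str, str, str], int] = {}

    for split, n_split in sorted(config.sizes.items()):
        chosen: List[QAPair] = []
        sources = sorted(weights_cfg)
        source_quota = _largest_remainder(n_split, [weights_cfg[s] for s in sources])
        for src, n_src in zip(sources, source_quota):
            tasks = sorted(
                {t for (sp, sg, t) in by_stratum if sp == split and sg == src},
                key=lambda t: t.value,
            )
            if not tasks or n_src == 0:
                if n_src:
                    shortfalls[(split, src, "*")] = n_src
                continue
            task_quota = _largest_remainder(n_src, [1.0 / len(tasks)] * len(tasks))
            for task, n_task in zip(tasks, task_quota):
                stratum = by_stratum.get((split, src, task), [])
                stratum = sorted(stratum, key=lambda qa: qa.qa_id)
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [seed, sum(split.encode()), sum(src.encode()), sum(task.value.encode())]
                    )
                )
                w = [sampling_weight(qa, freq) for qa in stratum]
                taken = _weighted_sample_wor(stratum, w, n_task, rng)
                key = (split, src, task.value)
                stratum_counts[key] = len(taken)
                if len(taken) < n_task:
                    shortfalls[key] = n_task - len(taken)
                for qa in taken:
                    chosen.append(qa)
        splits[split] = chosen
    return BenchmarkSplit(splits=splits, stratum_counts=stratum_counts, shortfalls=shortfalls)
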