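"""Knowledge-distillation kernel: temperature-softened KL loss and
top-left weight-crop student initialization with progressive shrinking.

The loss is

    L = KL( softmax(z_t / T) || softmax(z_s / T) ) * T^2

averaged over batch items, with KL(P||Q) = sum_i P(i) log(P(i)/Q(i)) in nats.
The T^2 factor keeps gradient magnitudes comparable across temperatures.

Students are initialized by cropping the leading rows/columns (the "top-left
corner") of the teacher's weight matrices, preserving part of the learned
representation; progressive shrinking trains a chain of students with strictly
decreasing hidden dimensions, each initialized by cropping its predecessor.

The kernel is exercised on small tanh feed-forward classifiers over synthetic
Gaussian inputs, with hand-derived gradients — large transformer students are
out of scope; the mathematics is the point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# core math

def softened_softmax(z: np.ndarray, T: float) -> np.ndarray:
    """Temperature-softened softmax along the last axis; T -> inf flattens
    toward uniform. Shift-invariant in the logits."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    zt = z / T
    zt = zt - zt.max(axis=-1, keepdims=True)
    e = np.exp(zt)
    return e / e.sum(axis=-1, keepdims=True)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P||Q) = sum_i P(i) log(P(i)/Q(i)) in nats, with 0*log 0 = 0.

    Raises if Q(i) = 0 where P(i) > 0 (support violation) or if either vector
    is not a probability distribution.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    for v in (P, Q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("inputs must be probability vectors summing to 1")
    mask = P > 0
    if np.any(Q[mask] == 0):
        raise ValueError("support violation: Q(i)=0 where P(i)>0")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


@dataclass(frozen=True)
class LogitBatch:
    z_t: np.ndarray  # (n_items, n_classes)
    z_s: np.ndarray  # same shape
    T: float = 1.0

    def __post_init__(self) -> None:
        if np.shape(self.z_t) != np.shape(self.z_s):
            raise ValueError("teacher/student logit shapes must match")
        if not (np.isfinite(self.T) and self.T > 0):
            raise ValueError("temperature must be finite and positive")


def distillation_loss(batch: LogitBatch) -> float:
    """Mean over items of KL(softmax(z_t/T) || softmax(z_s/T)) * T^2."""
    zt = np.atleast_2d(np.asarray(batch.z_t, dtype=float))
    zs = np.atleast_2d(np.asarray(batch.z_s, dtype=float))
    P = softened_softmax(zt, batch.T)
    Q = softened_softmax(zs, batch.T)
    per_item = np.sum(P * (np.log(P) - np.log(Q)), axis=-1)
    return float(per_item.mean() * batch.T ** 2)


# ---------------------------------------------------------------------------
# toy networks and weight cropping

def crop_matrix(W: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Leading (top-left) submatrix of W with the given shape."""
    W = np.asarray(W)
    if len(shape) != W.ndim or any(s > d for s, d in zip(shape, W.shape)):
        raise ValueError(f"crop shape {shape} exceeds teacher shape {W.shape}")
    return W[tuple(slice(0, s) for s in shape)].copy()


@dataclass
class MLPParams:
    """One-hidden-layer tanh classifier: logits = tanh(x W1 + b1) W2 + b2."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in (self.W1, self.b1, self.W2, self.b2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x @ self.W1 + self.b1) @ self.W2 + self.b2

    @staticmethod
    def random(d_in: int, hidden: int, n_classes: int, rng: np.random.Generator,
               scale: float = 1.5) -> "MLPParams":
        return MLPParams(
            W1=rng.normal(0, scale / np.sqrt(d_in), (d_in, hidden)),
            b1=rng.normal(0, 0.1, hidden),
            W2=rng.normal(0, scale / np.sqrt(hidden), (hidden, n_classes)),
            b2=rng.normal(0, 0.1, n_classes),
        )


def crop_initialize(teacher: MLPParams, hidden_dim: int) -> MLPParams:
    """Initialize a narrower student from the top-left corner of the teacher's
    weight matrices; input and output dimensions are preserved."""
    if hidden_dim > teacher.hidden_dim:
        raise ValueError("student hidden dim exceeds teacher's")
    return MLPParams(
        W1=crop_matrix(teacher.W1, (teacher.W1.shape[0], hidden_dim)),
        b1=crop_matrix(teacher.b1, (hidden_dim,)),
        W2=crop_matrix(teacher.W2, (hidden_dim, teacher.W2.shape[1])),
        b2=teacher.b2.copy(),
    )


# ---------------------------------------------------------------------------
# progressive distillation on synthetic inputs

def _loss_and_grads(student: MLPParams, x: np.ndarray, z_t: np.ndarray, T: float):
    h = np.tanh(x @ student.W1 + student.b1)
    z_s = h @ student.W2 + student.b2
    P = softened_softmax(z_t, T)
    Q = softened_softmax(z_s, T)
    loss = float(np.sum(P * (np.log(P) - np.log(Q)), axis=-1).mean() * T ** 2)
    n = x.shape[0]
    g_z = (Q - P) * T / n  # d(loss)/d(z_s)
    gW2 = h.T @ g_z
    gb2 = g_z.sum(axis=0)
    gh = g_z @ student.W2.T * (1.0 - h * h)
    gW1 = x.T @ gh
    gb1 = gh.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def train_student(
    student: MLPParams,
    teacher_fn: Callable[[np.ndarray], np.ndarray],
    data_gen: Callable[[np.random.Generator, int], np.ndarray],
    steps: int,
    rng: np.random.Generator,
    T: float = 2.0,
    lr: float = 0.05,
    batch_size: int = 256,
) -> Tuple[MLPParams, List[float]]:
    """Adam on the distillation loss against the teacher's logits."""
    params = [student.W1.copy(), student.b1.copy(), student.W2.copy(), student.b2.copy()]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    trace: List[float] = []
    for step in range(1, steps + 1):
        x = data_gen(rng, batch_size)
        z_t = teacher_fn(x)
        cur = MLPParams(*params)
        loss, grads = _loss_and_grads(cur, x, z_t, T)
        if not np.isfinite(loss):
            raise FloatingPointError(f"distillation diverged at step {step}: loss={loss}")
        trace.append(loss)
        for i, g in enumerate(grads):
            m[i] = b1m * m[i] + (1 - b1m) * g
            v[i] = b2m * v[i] + (1 - b2m) * g * g
            mh = m[i] / (1 - b1m ** step)
            vh = v[i] / (1 - b2m ** step)
            params[i] = params[i] - lr * mh / (np.sqrt(vh) + eps)
    return MLPParams(*params), trace


def gaussian_inputs(d_in: int) -> Callable[[np.random.Generator, int], np.ndarray]:
    def gen(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(0.0, 1.0, (n, d_in))

    return gen


def progressive_distill(
    teacher: MLPParams,
    schedule: Sequence[int],
    data_gen: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    steps: int = 500,
    seed: int = 0,
    T: float = 2.0,
    lr: float = 0.05,
) -> Tuple[List[MLPParams], List[List[float]]]:
    """Train a chain of progressively narrower students.

    The first student is cropped from the teacher, each subsequent one from
    the previous student; every student is trained to minimize the
    temperature-softened KL loss against the teacher's logits on synthetic
    inputs. Hidden dimensions must be non-increasing along the schedule.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    if any(b > a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule hidden dims must be non-increasing")
    if schedule[0] > teacher.hidden_dim:
        raise ValueError("first schedule dim exceeds teacher hidden dim")
    rng = np.random.default_rng(seed)
    data_gen = data_gen or gaussian_inputs(teacher.W1.shape[0])
    students: List[MLPParams] = []
    traces: List[List[float]] = []
    prev = teacher
    for hidden in schedule:
        student = crop_initialize(prev, hidden)
        student, trace = train_student(student, teacher.forward, data_gen, steps, rng, T=T, lr=lr)
        students.append(student)
        traces.append(trace)
        prev = student
    return students, traces


def agreement(a: MLPParams | Callable[[np.ndarray], np.ndarray], b: MLPParams, x: np.ndarray) -> float:
    """Fraction of inputs on which two models agree in argmax."""
    za = a(x) if callable(a) else a.forward(x)
    zb = b.forward(x)
    return float(np.mean(np.argmax(za, axis=1) == np.argmax(zb, axis=1)))
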