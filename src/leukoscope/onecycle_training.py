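"""Cyclical / one-cycle learning-rate machinery and the training loop.

The one-fit-cycle policy runs a single triangular learning-rate cycle — a
linear ascent from ``min_lr`` to ``max_lr`` over ``step_size`` iterations and
a symmetric linear descent back — followed by an annihilation tail in which
the rate keeps falling linearly to ``final_lr``, far below ``min_lr``. The
maximum bound comes from a learning-rate range test: a short pretraining run
with linearly increasing rate, whose smoothed loss curve bottoms out at the
largest rate that still trains and blows up shortly after. The minimum bound
is derived from the maximum by a fixed divisor (3-4 for repeated cycles,
10-20 when a single cycle is used).

The training loop is plain SGD with momentum (0.9) and weight decay (1e-4) on
softmax cross-entropy; the learning rate at iteration i is exactly
``lr_at(schedule, i)``, and batch order is a seed-deterministic shuffle per
epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .dense_model import Model


class ConfigurationError(ValueError):
    pass


# -- schedules -------------------------------------------------------------

@dataclass(frozen=True)
class OneCycleSchedule:
    min_lr: float
    max_lr: float
    step_size: int            # iterations per half-cycle
    total_iterations: int
    final_fraction: float     # share of iterations in the annihilation tail
    final_lr: float

    def __post_init__(self) -> None:
        if not 0.0 < self.min_lr < self.max_lr:
            raise ValueError(
                f"need 0 < min_lr < max_lr, got min_lr={self.min_lr}, max_lr={self.max_lr}"
            )
        if self.final_lr >= self.min_lr:
            raise ValueError("final_lr must be < min_lr")
        if 2 * self.step_size > self.total_iterations:
            raise ValueError("cycle (2*step_size) exceeds total_iterations")

    @property
    def tail(self) -> int:
        return self.total_iterations - 2 * self.step_size


@dataclass(frozen=True)
class ConstantSchedule:
    """Fixed learning rate, for baseline comparisons against one-cycle."""

    lr: float
    total_iterations: int

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


def build_schedule(min_lr: float, max_lr: float, total_iterations: int,
                   final_fraction: float = 0.1,
                   final_lr: float | None = None) -> OneCycleSchedule:
    """Partition the iteration budget into ascent, descent and tail.

    step_size = floor(total * (1 - final_fraction) / 2); the tail absorbs the
    remainder. final_lr defaults to min_lr / 100.
    """
    if min_lr >= max_lr:
        raise ValueError(f"min_lr ({min_lr}) must be < max_lr ({max_lr})")
    if total_iterations < 4:
        raise ValueError(f"total_iterations must be >= 4, got {total_iterations}")
    if not 0.0 <= final_fraction < 1.0:
        raise ValueError(f"final_fraction must be in [0, 1), got {final_fraction}")
    step_size = int(math.floor(total_iterations * (1.0 - final_fraction) / 2.0))
    if final_lr is None:
        final_lr = min_lr / 100.0
    return OneCycleSchedule(min_lr=min_lr, max_lr=max_lr, step_size=step_size,
                            total_iterations=total_iterations,
                            final_fraction=final_fraction, final_lr=final_lr)


def lr_at(schedule, iteration: int) -> float:
    """Learning rate at an iteration index; piecewise linear and continuous."""
    if not 0 <= iteration < schedule.total_iterations:
        raise IndexError(
            f"iteration {iteration} out of range [0, {schedule.total_iterations})"
        )
    if isinstance(schedule, ConstantSchedule):
        return schedule.lr
    s = schedule.step_size
    if iteration <= s:
        if s == 0:
            return schedule.max_lr
        return schedule.min_lr + (schedule.max_lr - schedule.min_lr) * iteration / s
    if iteration <= 2 * s:
        return schedule.max_lr - (schedule.max_lr - schedule.min_lr) * (iteration - s) / s
    # annihilation tail: linear min_lr -> final_lr over the remaining iterations
    tail = schedule.total_iterations - 1 - 2 * s
    j = iteration - 2 * s
    return schedule.min_lr + (schedule.final_lr - schedule.min_lr) * j / tail


def lr_trace(schedule) -> np.ndarray:
    return np.array([lr_at(schedule, i) for i in range(schedule.total_iterations)])


# -- learning-rate range test ----------------------------------------------

@dataclass(frozen=True)
class RangeTestResult:
    lrs: np.ndarray
    losses: np.ndarray          # smoothed losses
    raw_losses: np.ndarray
    diverged_at: int | None
    suggested_max: float | None


def lr_range_test(step_fn, lr_start: float, lr_end: float, n_iterations: int,
                  smoothing: float = 0.98, divergence_factor: float = 4.0,
                  log_spacing: bool = False) -> RangeTestResult:
    """Probe increasing learning rates until the smoothed loss diverges.

    ``step_fn(lr) -> loss`` performs one optimization step at the given rate.
    Losses are exponentially smoothed (bias-corrected); the test stops early
    once the smoothed loss exceeds ``divergence_factor`` times the best
    smoothed loss seen, or the raw loss goes non-finite. ``suggested_max`` is
    the rate at the smoothed-loss minimum — the last reliably trainable rate.
    """
    if not 0.0 < lr_start < lr_end:
        raise ValueError("need 0 < lr_start < lr_end")
    if n_iterations < 10:
        raise ValueError(f"n_iterations must be >= 10, got {n_iterations}")
    if not 0.0 <= smoothing < 1.0:
        raise ValueError("smoothing must be in [0, 1)")
    if divergence_factor <= 1.0:
        raise ValueError("divergence_factor must be > 1")

    if log_spacing:
        grid = np.geomspace(lr_start, lr_end, n_iterations)
    else:
        grid = np.linspace(lr_start, lr_end, n_iterations)

    lrs: list[float] = []
    raw: list[float] = []
    smoothed: list[float] = []
    avg = 0.0
    best = math.inf
    diverged_at: int | None = None
    for i, lr in enumerate(grid):
        loss = float(step_fn(float(lr)))
        lrs.append(float(lr))
        raw.append(loss)
        if not math.isfinite(loss):
            smoothed.append(math.inf)
            diverged_at = i
            break
        avg = smoothing * avg + (1.0 - smoothing) * loss
        sm = avg / (1.0 - smoothing ** (i + 1))
        smoothed.append(sm)
        best = min(best, sm)
        if sm > divergence_factor * best:
            diverged_at = i
            break

    smoothed_arr = np.array(smoothed)
    finite = np.isfinite(smoothed_arr)
    suggested = float(np.array(lrs)[finite][np.argmin(smoothed_arr[finite])]) \
        if finite.any() else None
    return RangeTestResult(lrs=np.array(lrs), losses=smoothed_arr,
                           raw_losses=np.array(raw), diverged_at=diverged_at,
                           suggested_max=suggested)


def replay_stopping_rule(losses, smoothing: float = 0.98,
                         divergence_factor: float = 4.0) -> int | None:
    """Apply the range-test stopping rule to a recorded loss sequence.

    Pure function of the losses; replaying a test's raw losses reproduces its
    ``diverged_at`` exactly.
    """
    avg = 0.0
    best = math.inf
    for i, loss in enumerate(losses):
        if not math.isfinite(loss):
            return i
        avg = smoothing * avg + (1.0 - smoothing) * float(loss)
        sm = avg / (1.0 - smoothing ** (i + 1))
        best = min(best, sm)
        if sm > divergence_factor * best:
            return i
    return None


BOUND_POLICIES = ("factor3_4", "factor10_20_one_cycle")


def suggest_bounds(result: RangeTestResult, policy: str = "factor10_20_one_cycle"):
    """(min_lr, max_lr) from a range test: max at the loss minimum, min a
    fixed divisor below (3.5 for repeated cycles, 15 for a single cycle —
    midpoints of the 3-4 and 10-20 ranges)."""
    if result.suggested_max is None:
        raise ValueError("range test produced no usable suggested_max")
    if policy not in BOUND_POLICIES:
        raise ValueError(f"policy must be one of {BOUND_POLICIES}, got {policy!r}")
    max_lr = result.suggested_max
    divisor = 3.5 if policy == "factor3_4" else 15.0
    return max_lr / divisor, max_lr


def quick_lr_probe(make_step_fn, candidate_lrs, n_iterations: int = 200,
                   divergence_factor: float = 4.0) -> float:
    """Manual bound helper: run a short constant-rate trial per candidate and
    return the largest rate whose loss never triggers the divergence rule."""
    best = None
    for lr in sorted(float(l) for l in candidate_lrs):
        step_fn = make_step_fn()
        losses = [float(step_fn(lr)) for _ in range(n_iterations)]
        if replay_stopping_rule(losses, divergence_factor=divergence_factor) is None:
            best = lr
    if best is None:
        raise ValueError("no candidate learning rate converged")
    return best


# -- training loop ----------------------------------------------------------

@dataclass
class TrainHistory:
    iteration_lr: list[float] = field(default_factory=list)
    iteration_loss: list[float] = field(default_factory=list)
    epoch_train_acc: list[float] = field(default_factory=list)
    epoch_val_acc: list[float] = field(default_factory=list)
    epoch_train_loss: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)

    def iterations_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": range(len(self.iteration_lr)),
            "lr": self.iteration_lr,
            "loss": self.iteration_loss,
        })

    def epochs_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": range(len(self.epoch_train_acc)),
            "train_acc": self.epoch_train_acc,
            "val_acc": self.epoch_val_acc,
            "train_loss": self.epoch_train_loss,
            "val_loss": self.epoch_val_loss,
        })


def _stack_items(items) -> tuple[np.ndarray, np.ndarray]:
    """Accept SyntheticSamples, (image, label) pairs, or (X, y) arrays."""
    images, labels = [], []
    for it in items:
        if hasattr(it, "image") and hasattr(it, "label"):
            images.append(np.asarray(it.image, dtype=float))
            labels.append(it.label.index if hasattr(it.label, "index") else int(it.label))
        else:
            img, lab = it
            images.append(np.asarray(img, dtype=float))
            labels.append(lab.index if hasattr(lab, "index") else int(lab))
    x = np.stack(images).transpose(0, 3, 1, 2).astype(nn.DTYPE)
    y = np.array(labels, dtype=np.int64)
    return x, y


def _evaluate_batched(model: Model, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i:i + batch_size], train=False)
        loss, _ = nn.cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * (logits.shape[0]))
        correct += int((np.argmax(logits, axis=1) == y[i:i + batch_size]).sum())
    return correct / x.shape[0], float(np.sum(losses) / x.shape[0])


def iterations_per_epoch(n_items: int, batch_size: int) -> int:
    return int(math.ceil(n_items / batch_size))


def train(model: Model, train_items, val_items, schedule, epochs: int,
          batch_size: int, seed: int, momentum: float = 0.9,
          weight_decay: float = 1e-4) -> tuple[Model, TrainHistory]:
    """Train with the given learning-rate schedule; deterministic in seed.

    ``schedule.total_iterations`` must equal epochs * ceil(n_train / batch).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    history = TrainHistory()
    if epochs == 0:
        return model, history
    x, y = _stack_items(train_items)
    xv, yv = _stack_items(val_items)
    n = x.shape[0]
    expected = epochs * iterations_per_epoch(n, batch_size)
    if schedule.total_iterations != expected:
        raise ConfigurationError(
            f"schedule.total_iterations = {schedule.total_iterations} but "
            f"epochs * ceil(n/batch) = {expected}"
        )
    opt = nn.SGD(model.trainable_parameters(), momentum=momentum,
                 weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    it = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            lr = lr_at(schedule, it)
            logits = model.forward(x[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step(lr)
            history.iteration_lr.append(lr)
            history.iteration_loss.append(loss)
            it += 1
        tr_acc, tr_loss = _evaluate_batched(model, x, y)
        va_acc, va_loss = _evaluate_batched(model, xv, yv)
        history.epoch_train_acc.append(tr_acc)
        history.epoch_val_acc.append(va_acc)
        history.epoch_train_loss.append(tr_loss)
        history.epoch_val_loss.append(va_loss)
    return model, history


def iterations_to_accuracy(history: TrainHistory, target: float,
                           iterations_per_epoch_: int) -> float:
    """First iteration count at which validation accuracy reached target
    (epoch granularity); inf if it never did."""
    for e, acc in enumerate(history.epoch_val_acc):
        if acc >= target:
            return (e + 1) * iterations_per_epoch_
    return math.inf
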