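"""Cyclical learning-rate schedules (triangular and SGDR cosine annealing).

Two schedule shapes cover both training stages of the pipeline:

* ``circular`` — piecewise linear within each cycle: the rate climbs from
  ``min_lr`` to ``max_lr`` over ``epochs_up`` epochs, then decays linearly
  back to ``min_lr`` over ``epochs_down`` epochs.
* ``cosine_anneal`` — warm restarts: each cycle starts at ``max_lr`` and
  follows a half cosine down to ``min_lr`` over the cycle length
  (``epochs_up + epochs_down``).

Rates are per layer-group, so differential learning rates across the first,
middle and last thirds of a network are one schedule with vector
``max_lr``/``min_lr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LRScheduleSpec",
    "scheduled_lr",
    "fullscale_classifier_cycle_lengths",
]


@dataclass(frozen=True)
class LRScheduleSpec:
    """One cyclical learning-rate schedule.

    Parameters
    ----------
    kind:
        ``"circular"`` (triangular, linear up then down) or
        ``"cosine_anneal"`` (half-cosine decay from max to min per cycle).
    max_lr, min_lr:
        Learning rates per layer group (scalars broadcast to one group).
    epochs_up, epochs_down:
        Lengths (in epochs, fractional allowed) of the rising and falling
        phases.  The cosine kind uses their sum as the cycle length.
    cycles:
        Number of identical cycles (warm restarts).
    """

    kind: str
    max_lr: tuple[float, ...]
    min_lr: tuple[float, ...]
    epochs_up: float
    epochs_down: float
    cycles: int = 1

    def __post_init__(self):
        if self.kind not in ("circular", "cosine_anneal"):
            raise ValueError(f"unknown schedule kind: {self.kind!r}")
        object.__setattr__(self, "max_lr", tuple(np.atleast_1d(self.max_lr).astype(float)))
        object.__setattr__(self, "min_lr", tuple(np.atleast_1d(self.min_lr).astype(float)))
        if len(self.max_lr) != len(self.min_lr):
            raise ValueError("max_lr and min_lr must have the same length")
        if any(lo > hi for lo, hi in zip(self.min_lr, self.max_lr)):
            raise ValueError("min_lr must be <= max_lr elementwise")
        if self.epochs_up + self.epochs_down <= 0:
            raise ValueError("epochs_up + epochs_down must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    @property
    def cycle_epochs(self) -> float:
        return self.epochs_up + self.epochs_down

    @property
    def total_epochs(self) -> float:
        return self.cycle_epochs * self.cycles


def scheduled_lr(step: int, schedule: LRScheduleSpec, steps_per_epoch: int) -> np.ndarray:
    """Learning rate(s) at a global step index.

    ``step`` counts optimizer updates from the start of the schedule; the
    boundary step equal to the total number of scheduled steps is allowed
    (it evaluates the cycle endpoint), anything beyond raises — a step past
    the schedule signals a bookkeeping bug in the training loop.
    """
    if steps_per_epoch < 1:
        raise ValueError("steps_per_epoch must be >= 1")
    total_steps = schedule.total_epochs * steps_per_epoch
    if step < 0 or step > total_steps + 1e-9:
        raise ValueError(
            f"step {step} outside schedule of {total_steps:g} total steps"
        )
    cycle_steps = schedule.cycle_epochs * steps_per_epoch
    t = step % cycle_steps  # position within the cycle, in steps
    if step == total_steps:  # boundary: evaluate the end of the last cycle
        t = cycle_steps
    lo = np.asarray(schedule.min_lr)
    hi = np.asarray(schedule.max_lr)
    if schedule.kind == "circular":
        up = schedule.epochs_up * steps_per_epoch
        down = schedule.epochs_down * steps_per_epoch
        if up > 0 and t <= up:
            frac = t / up
            return lo + (hi - lo) * frac
        frac = (t - up) / down if down > 0 else 1.0
        return hi - (hi - lo) * frac
    # cosine annealing: max -> min over the cycle
    frac = t / cycle_steps
    return lo + 0.5 * (hi - lo) * (1.0 + np.cos(np.pi * frac))


def fullscale_classifier_cycle_lengths(n_sets: int = 17, lengths: tuple[int, ...] = (1, 2, 4)) -> list[int]:
    """Cycle-length ledger of the full-size classifier training stage.

    The all-layer stage runs ``n_sets`` sets of warm-restart cycles of
    increasing length; the defaults enumerate 51 cycles totalling 119 epochs.
    """
    return list(lengths) * n_sets
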