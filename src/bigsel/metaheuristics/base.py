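"""Shared infrastructure for the population/agent-based optimizers.

All six algorithms minimize a black-box fitness over a box-bounded real
search space through a common :func:`minimize` front end.  A tracker
wraps the user fitness: it counts evaluations, rejects non-finite
returns, enforces an optional evaluation budget, and maintains the
best-so-far agent outside each algorithm's own population, so the
reported per-iteration trace is non-increasing for every algorithm
(BAS and FFO are not intrinsically monotone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Agent", "OptimizerRun", "NonFiniteFitnessError", "Tracker", "clip"]


class NonFiniteFitnessError(ValueError):
    """The fitness callback returned NaN or infinity."""


class BudgetExhausted(Exception):
    """Internal control-flow signal: the evaluation budget is spent."""


@dataclass
class Agent:
    """A candidate solution: a real position and its (minimized) fitness."""

    position: np.ndarray
    fitness: float

    def copy(self) -> "Agent":
        return Agent(self.position.copy(), self.fitness)


@dataclass
class OptimizerRun:
    """Result of one optimizer run: best agent, per-iteration best-so-far
    trace, and the number of fitness evaluations spent."""

    best_position: np.ndarray
    best_fitness: float
    trace: list[float]
    evaluations: int
    seed: int


def clip(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(x, lo, hi)


class Tracker:
    """Budgeted, validated fitness evaluator with best-so-far bookkeeping."""

    def __init__(self, fitness, lo: float, hi: float, max_evals: int | None = None):
        self._fitness = fitness
        self.lo = lo
        self.hi = hi
        self.max_evals = max_evals
        self.evaluations = 0
        self.best_position: np.ndarray | None = None
        self.best_fitness = np.inf
        self.trace: list[float] = []

    def evaluate(self, x: np.ndarray, record: bool = True) -> float:
        """Evaluate the fitness at ``x``.

        ``record=False`` still counts the evaluation and validates the
        value but leaves best-so-far untouched (used for sensing probes
        that may sit outside the box).
        """
        if self.max_evals is not None and self.evaluations >= self.max_evals:
            raise BudgetExhausted
        f = float(self._fitness(np.asarray(x, dtype=float)))
        self.evaluations += 1
        if not np.isfinite(f):
            raise NonFiniteFitnessError(
                f"fitness returned non-finite value {f!r} at position {np.asarray(x)}"
            )
        if record and f < self.best_fitness:
            self.best_fitness = f
            self.best_position = np.asarray(x, dtype=float).copy()
        return f

    def end_iteration(self) -> None:
        self.trace.append(self.best_fitness)
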