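"""Fruit fly optimization (FFO).

A swarm center scatters candidate flies with uniform random offsets of
magnitude at most the scatter radius (the original two-coordinate
formulation generalized to d dimensions).  Each candidate's smell
concentration judgement value SC = 1 / Distance (Euclidean norm of the
candidate position, epsilon-guarded at the origin) is computed, the
fitness at the candidate position is the smell the search actually
optimizes, and the center relocates to the best candidate only when it
beats the historical best.  The scatter radius decays geometrically so
the vision stage can refine; radius 0 degenerates to a frozen swarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, Tracker, clip

__all__ = ["FfoConfig", "smell_concentration", "ffo_step", "run"]

_EPS = 1e-12


@dataclass
class FfoConfig:
    swarm_size: int = 10
    max_iter: int = 400
    scatter_radius: float = 0.3
    scatter_radius_final: float = 1e-3

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.scatter_radius < 0:
            raise ValueError("scatter_radius must be >= 0")


def smell_concentration(position: np.ndarray) -> float:
    """SC = reciprocal of the Euclidean distance to the origin."""
    return 1.0 / (float(np.linalg.norm(position)) + _EPS)


def ffo_step(
    center: np.ndarray,
    config: FfoConfig,
    fitness,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 1.0,
    radius: float | None = None,
    best_fitness: float = np.inf,
) -> tuple[np.ndarray, Agent, np.ndarray]:
    """Scatter, evaluate, and (conditionally) relocate the center.

    Returns the new center, the best candidate of this scatter, and the
    SC values of all candidates.
    """
    r = config.scatter_radius if radius is None else radius
    d = center.size
    offsets = rng.uniform(-r, r, size=(config.swarm_size, d))
    candidates = clip(center + offsets, lo, hi)
    sc = np.array([smell_concentration(c) for c in candidates])
    fits = np.array([fitness(c) for c in candidates])
    i = int(np.argmin(fits))
    best = Agent(candidates[i].copy(), float(fits[i]))
    if best.fitness < best_fitness:
        center = best.position.copy()
    return center, best, sc


def run(tracker: Tracker, d: int, config: FfoConfig, rng: np.random.Generator) -> None:
    lo, hi = tracker.lo, tracker.hi
    center = rng.uniform(lo, hi, d)
    tracker.evaluate(center)
    decay = (
        (config.scatter_radius_final / config.scatter_radius)
        ** (1 / max(config.max_iter - 1, 1))
        if config.scatter_radius > 0
        else 1.0
    )
    tracker.end_iteration()
    for i in range(config.max_iter):
        radius = config.scatter_radius * decay**i
        center, _, _ = ffo_step(
            center, config, tracker.evaluate, rng, lo, hi, radius, tracker.best_fitness
        )
        tracker.end_iteration()
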