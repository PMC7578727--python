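"""Crow search optimization (CSO).

Each crow remembers the best position it has visited.  Per iteration a
crow picks a random other crow and either pursues that crow's memory
(moving by r * fl toward it, when the awareness draw r is >= the
awareness probability AP) or, having been noticed, evades to a uniform
random position in the box.  A crow's memory is replaced only when the
new position improves on it, so per-crow memory fitness is
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, Tracker, clip

__all__ = ["CsoConfig", "cso_step", "run"]


@dataclass
class CsoConfig:
    flock_size: int = 20
    max_iter: int = 200
    ap: float = 0.1
    fl: float = 2.0

    def __post_init__(self) -> None:
        if self.flock_size < 2:
            raise ValueError("flock_size must be >= 2")
        if not (0 <= self.ap <= 1):
            raise ValueError("awareness probability must lie in [0, 1]")


def cso_step(
    crows: list[Agent],
    memories: list[Agent],
    config: CsoConfig,
    rng: np.random.Generator,
    fitness,
    lo: float = 0.0,
    hi: float = 1.0,
) -> tuple[list[Agent], list[Agent]]:
    """One pursuit/evasion sweep over the flock."""
    m = len(crows)
    if m < 2:
        raise ValueError("flock must have >= 2 crows")
    crows = [a.copy() for a in crows]
    memories = [a.copy() for a in memories]
    d = crows[0].position.size
    for j in range(m):
        k = int(rng.integers(m - 1))
        if k >= j:
            k += 1
        r = float(rng.uniform())
        if r >= config.ap:
            pos = crows[j].position + r * config.fl * (
                memories[k].position - crows[j].position
            )
        else:
            pos = rng.uniform(lo, hi, d)
        pos = clip(pos, lo, hi)
        f = fitness(pos)
        crows[j] = Agent(pos, f)
        if f < memories[j].fitness:
            memories[j] = Agent(pos.copy(), f)
    return crows, memories


def run(tracker: Tracker, d: int, config: CsoConfig, rng: np.random.Generator) -> None:
    lo, hi = tracker.lo, tracker.hi
    crows = []
    for _ in range(config.flock_size):
        pos = rng.uniform(lo, hi, d)
        crows.append(Agent(pos, tracker.evaluate(pos)))
    memories = [a.copy() for a in crows]
    tracker.end_iteration()
    for _ in range(config.max_iter):
        crows, memories = cso_step(crows, memories, config, rng, tracker.evaluate, lo, hi)
        tracker.end_iteration()
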