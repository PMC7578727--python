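"""Teaching-learning-based optimization (TLBO).

Teacher phase: every learner moves by a random fraction of the gap
between the class best (the teacher) and the teaching-factor-scaled
class mean; the move is kept only if it improves the learner.  Learner
phase: each learner pairs with a random distinct partner and moves
toward the better / away from the worse of the two, again with greedy
acceptance.  The teaching factor is fixed at 2 by default, or drawn as
round(1 + u) with u uniform on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, Tracker, clip

__all__ = ["TlboConfig", "tlbo_teaching_factor", "tlbo_step", "run"]


@dataclass
class TlboConfig:
    pop_size: int = 20
    generations: int = 80
    tf_mode: str = "fixed-2"

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.tf_mode not in ("fixed-2", "random"):
            raise ValueError(f"unknown tf_mode {self.tf_mode!r}")


def tlbo_teaching_factor(rng: np.random.Generator, mode: str = "fixed-2") -> int:
    """Teaching factor T_F in {1, 2}; 2 in fixed mode."""
    if mode == "fixed-2":
        return 2
    return int(round(1 + rng.uniform() * (2 - 1)))


def tlbo_step(
    population: list[Agent],
    config: TlboConfig,
    rng: np.random.Generator,
    fitness,
    lo: float = 0.0,
    hi: float = 1.0,
) -> list[Agent]:
    """One teacher-phase plus learner-phase sweep with greedy acceptance."""
    pop = [a.copy() for a in population]
    n = len(pop)
    if n < 2:
        raise ValueError("population must have >= 2 learners")
    d = pop[0].position.size

    # teacher phase
    mean = np.mean([a.position for a in pop], axis=0)
    teacher = min(pop, key=lambda a: a.fitness)
    tf = tlbo_teaching_factor(rng, config.tf_mode)
    for j in range(n):
        r = rng.uniform(size=d)
        cand = clip(pop[j].position + r * (teacher.position - tf * mean), lo, hi)
        f = fitness(cand)
        if f < pop[j].fitness:
            pop[j] = Agent(cand, f)

    # learner phase
    for j in range(n):
        k = int(rng.integers(n - 1))
        if k >= j:
            k += 1
        r = rng.uniform(size=d)
        if pop[k].fitness < pop[j].fitness:
            cand = pop[j].position + r * (pop[k].position - pop[j].position)
        else:
            cand = pop[j].position + r * (pop[j].position - pop[k].position)
        cand = clip(cand, lo, hi)
        f = fitness(cand)
        if f < pop[j].fitness:
            pop[j] = Agent(cand, f)
    return pop


def run(tracker: Tracker, d: int, config: TlboConfig, rng: np.random.Generator) -> None:
    lo, hi = tracker.lo, tracker.hi
    pop = []
    for _ in range(config.pop_size):
        pos = rng.uniform(lo, hi, d)
        pop.append(Agent(pos, tracker.evaluate(pos)))
    tracker.end_iteration()
    for _ in range(config.generations):
        pop = tlbo_step(pop, config, rng, tracker.evaluate, lo, hi)
        tracker.end_iteration()
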