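"""Invasive weed optimization (IWO).

Each weed spawns a fitness-proportional number of seeds (linear
interpolation between ``a_max`` for the colony best and ``a_min`` for
the worst), dispersed around the parent with Gaussian noise whose
standard deviation decays over iterations under a nonlinear modulation
index ``m``.  The merged colony is truncated to the best ``c_max``
weeds (competitive exclusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base import Agent, Tracker, clip

__all__ = ["IwoConfig", "iwo_seed_count", "iwo_sigma", "iwo_step", "run"]


@dataclass
class IwoConfig:
    pop_init: int = 8
    c_max: int = 20
    a_min: int = 1
    a_max: int = 4
    sigma_initial: float = 0.25
    sigma_final: float = 1e-3
    m: float = 3.0
    t_max: int = 60

    def __post_init__(self) -> None:
        if self.a_min > self.a_max:
            raise ValueError(f"a_min ({self.a_min}) must be <= a_max ({self.a_max})")
        if self.sigma_final > self.sigma_initial:
            raise ValueError("sigma_final must be <= sigma_initial")
        if self.c_max < self.pop_init:
            raise ValueError("c_max must be >= pop_init")


def iwo_seed_count(
    fit: float, minfit: float, maxfit: float, a_min: int, a_max: int
) -> int:
    """Seeds for a weed of fitness ``fit``: linear between the colony
    extremes, floored to an integer; the best weed gets ``a_max``.

    If all weeds share one fitness value the degenerate rule returns
    ``a_max``.
    """
    if a_min > a_max:
        raise ValueError(f"a_min ({a_min}) must be <= a_max ({a_max})")
    if minfit == maxfit:
        return a_max
    raw = (a_max * (maxfit - fit) + a_min * (fit - minfit)) / (maxfit - minfit)
    return int(min(max(math.floor(raw), a_min), a_max))


def iwo_sigma(
    t: int, t_max: int, m: float, sigma_initial: float, sigma_final: float
) -> float:
    """Dispersal standard deviation at iteration ``t`` of ``t_max``."""
    return ((t_max - t) / t_max) ** m * (sigma_initial - sigma_final) + sigma_final


def iwo_step(
    population: list[Agent],
    config: IwoConfig,
    t: int,
    rng: np.random.Generator,
    fitness,
    lo: float = 0.0,
    hi: float = 1.0,
) -> list[Agent]:
    """One reproduction/dispersal/exclusion cycle."""
    if not population:
        raise ValueError("empty population")
    fits = [a.fitness for a in population]
    minfit, maxfit = min(fits), max(fits)
    sigma = iwo_sigma(t, config.t_max, config.m, config.sigma_initial, config.sigma_final)
    offspring: list[Agent] = []
    for agent in population:
        n_seeds = iwo_seed_count(agent.fitness, minfit, maxfit, config.a_min, config.a_max)
        for _ in range(n_seeds):
            pos = clip(agent.position + rng.normal(0.0, sigma, agent.position.size), lo, hi)
            offspring.append(Agent(pos, fitness(pos)))
    merged = population + offspring
    merged.sort(key=lambda a: a.fitness)  # stable: parents precede equal children
    return merged[: config.c_max]


def run(tracker: Tracker, d: int, config: IwoConfig, rng: np.random.Generator) -> None:
    lo, hi = tracker.lo, tracker.hi
    pop = []
    for _ in range(config.pop_init):
        pos = rng.uniform(lo, hi, d)
        pop.append(Agent(pos, tracker.evaluate(pos)))
    tracker.end_iteration()
    for t in range(1, config.t_max + 1):
        pop = iwo_step(pop, config, t, rng, tracker.evaluate, lo, hi)
        tracker.end_iteration()
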