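"""League championship optimization (LCO).

Teams (solutions) meet in a single round-robin schedule per season
(circle method).  A match between teams j and k is resolved by drawing
u ~ U(0, 1) against the idealized win probability

    C_j = (f_k - f_hat) / (f_j + f_k - 2 f_hat),

where f_hat is a common reference ("ideal") fitness at or below every
attainable value; lower own fitness means higher win probability and
C_j + C_k = 1.  The source formulation gives no formation-update
equation, so a documented surrogate is used: the loser moves a fixed
fraction of the way toward the winner plus Gaussian jitter, accepted
only on improvement.  Jitter decays per season so late seasons refine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, Tracker, clip

__all__ = ["LcoConfig", "lco_schedule", "lco_win_probability", "lco_play_match", "lco_step", "run"]


@dataclass
class LcoConfig:
    teams: int = 10
    seasons: int = 60
    f_hat: float = 0.0
    update_step: float = 0.5
    jitter_initial: float = 0.1
    jitter_final: float = 1e-3

    def __post_init__(self) -> None:
        if self.teams < 2 or self.teams % 2:
            raise ValueError(f"teams must be an even integer >= 2, got {self.teams}")
        if self.seasons < 1:
            raise ValueError("seasons must be >= 1")


def lco_schedule(a: int) -> list[list[tuple[int, int]]]:
    """Single round-robin pairings (circle method): ``a - 1`` weeks, every
    team once per week, every unordered pair exactly once."""
    if a < 2 or a % 2:
        raise ValueError(f"team count must be an even integer >= 2, got {a}")
    ids = list(range(a))
    weeks = []
    for _ in range(a - 1):
        weeks.append([(ids[i], ids[a - 1 - i]) for i in range(a // 2)])
        ids = [ids[0]] + [ids[-1]] + ids[1:-1]
    return weeks


def lco_win_probability(f_j: float, f_k: float, f_hat: float) -> float:
    """Probability that team j (fitness ``f_j``) beats team k.

    Both teams exactly at the ideal point is resolved as 0.5 by
    convention.
    """
    if f_j < f_hat or f_k < f_hat:
        raise ValueError("team fitnesses must be >= the reference f_hat")
    denom = f_j + f_k - 2 * f_hat
    if denom == 0:
        return 0.5
    return (f_k - f_hat) / denom


def lco_play_match(
    f_j: float, f_k: float, f_hat: float, rng: np.random.Generator
) -> bool:
    """Resolve one match; True when team j wins (u <= C_j)."""
    return float(rng.uniform()) <= lco_win_probability(f_j, f_k, f_hat)


def lco_step(
    teams: list[Agent],
    week: list[tuple[int, int]],
    config: LcoConfig,
    rng: np.random.Generator,
    fitness,
    lo: float = 0.0,
    hi: float = 1.0,
    jitter: float | None = None,
) -> list[Agent]:
    """Play one scheduled week; losers attempt a move toward winners."""
    teams = [a.copy() for a in teams]
    jit = config.jitter_initial if jitter is None else jitter
    for j, k in week:
        f_j, f_k = teams[j].fitness, teams[k].fitness
        f_hat = min(config.f_hat, f_j, f_k)  # keep the reference attainable
        winner, loser = (j, k) if lco_play_match(f_j, f_k, f_hat, rng) else (k, j)
        d = teams[loser].position.size
        cand = (
            teams[loser].position
            + config.update_step * (teams[winner].position - teams[loser].position)
            + rng.normal(0.0, jit, d)
        )
        cand = clip(cand, lo, hi)
        f = fitness(cand)
        if f < teams[loser].fitness:
            teams[loser] = Agent(cand, f)
    return teams


def run(tracker: Tracker, d: int, config: LcoConfig, rng: np.random.Generator) -> None:
    lo, hi = tracker.lo, tracker.hi
    teams = []
    for _ in range(config.teams):
        pos = rng.uniform(lo, hi, d)
        teams.append(Agent(pos, tracker.evaluate(pos)))
    schedule = lco_schedule(config.teams)
    decay = (config.jitter_final / config.jitter_initial) ** (1 / max(config.seasons - 1, 1))
    tracker.end_iteration()
    for season in range(config.seasons):
        jitter = config.jitter_initial * decay**season
        for week in schedule:
            teams = lco_step(teams, week, config, rng, tracker.evaluate, lo, hi, jitter)
        tracker.end_iteration()
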