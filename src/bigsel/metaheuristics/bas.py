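"""Beetle antennae search (BAS).

Each beetle probes the fitness at two antenna tips placed symmetrically
along a random unit direction, then steps a distance delta along that
direction toward the better tip.  Antenna length and step size decay
every iteration: s' = c1*s + 0.01 (an affine map with fixed point
0.01/(1 - c1)) and delta' = c2*delta.  With the default movement
convention ``m_dir = -1`` the beetle moves toward the lower-fitness
antenna; the opposite convention is selectable.

Antenna probes are evaluated without box clipping so the exact
symmetry z_r - z = -(z_l - z) holds at the boundary; probes count
toward the evaluation budget but only (clipped) beetle positions update
the best-so-far record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, Tracker, clip

__all__ = ["BasConfig", "bas_decay", "bas_step", "run"]


@dataclass
class BasConfig:
    n_beetles: int = 3
    i_max: int = 500
    s0: float = 0.2
    delta0: float = 0.3
    c1: float = 0.95
    c2: float = 0.98
    m_dir: int = -1

    def __post_init__(self) -> None:
        if not (0 < self.c1 < 1 and 0 < self.c2 < 1):
            raise ValueError("c1 and c2 must lie in (0, 1)")
        if self.m_dir not in (-1, 1):
            raise ValueError("m_dir must be -1 or +1")


def bas_decay(s: float, delta: float, c1: float, c2: float) -> tuple[float, float]:
    """One decay step of antenna length and search step size."""
    if not (0 < c1 < 1 and 0 < c2 < 1):
        raise ValueError("c1 and c2 must lie in (0, 1)")
    return c1 * s + 0.01, c2 * delta


def bas_step(
    beetle: Agent,
    state: tuple[float, float],
    fitness,
    config: BasConfig,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 1.0,
    probe=None,
) -> tuple[Agent, tuple[float, float]]:
    """One antenna-sensing move.

    ``state`` is (antenna length s, step size delta), both > 0; it is
    returned unchanged (decay is applied separately).  ``probe``
    defaults to ``fitness`` and is used for the (possibly out-of-box)
    antenna evaluations.
    """
    s, delta = state
    if s <= 0 or delta <= 0:
        raise ValueError("antenna length and step size must be > 0")
    probe = probe or fitness
    d = beetle.position.size
    while True:
        r = rng.standard_normal(d)
        norm = np.linalg.norm(r)
        if norm > 0:
            break
    q = r / norm
    z_r = beetle.position + s * q
    z_l = beetle.position - s * q
    sg = np.sign(probe(z_r) - probe(z_l))
    if sg == 0:
        return beetle.copy(), state
    new_pos = clip(beetle.position + config.m_dir * delta * q * sg, lo, hi)
    return Agent(new_pos, fitness(new_pos)), state


def run(tracker: Tracker, d: int, config: BasConfig, rng: np.random.Generator) -> None:
    lo, hi = tracker.lo, tracker.hi
    beetles = []
    for _ in range(config.n_beetles):
        pos = rng.uniform(lo, hi, d)
        beetles.append(Agent(pos, tracker.evaluate(pos)))
    states = [(config.s0, config.delta0)] * config.n_beetles
    probe = lambda x: tracker.evaluate(x, record=False)  # noqa: E731
    tracker.end_iteration()
    for _ in range(config.i_max):
        for b in range(config.n_beetles):
            beetles[b], _ = bas_step(
                beetles[b], states[b], tracker.evaluate, config, rng, lo, hi, probe
            )
            states[b] = bas_decay(*states[b], config.c1, config.c2)
        tracker.end_iteration()
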