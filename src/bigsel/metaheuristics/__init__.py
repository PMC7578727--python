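"""Six population/agent-based black-box minimizers under one interface.

Algorithms: invasive weed optimization (``iwo``), teaching-learning-based
optimization (``tlbo``), league championship optimization (``lco``),
beetle antennae search (``baso``), crow search (``cso``) and fruit fly
optimization (``ffo``).  All share a box-bounded real search space,
seeded determinism, and best-so-far tracking with a non-increasing
per-iteration trace.
"""

from __future__ import annotations

import numpy as np

from . import bas, cso, ffo, iwo, lco, tlbo
from .base import (
    Agent,
    BudgetExhausted,
    NonFiniteFitnessError,
    OptimizerRun,
    Tracker,
)
from .bas import BasConfig, bas_decay, bas_step
from .cso import CsoConfig, cso_step
from .ffo import FfoConfig, ffo_step, smell_concentration
from .iwo import IwoConfig, iwo_seed_count, iwo_sigma, iwo_step
from .lco import LcoConfig, lco_play_match, lco_schedule, lco_step, lco_win_probability
from .tlbo import TlboConfig, tlbo_step, tlbo_teaching_factor

__all__ = [
    "ALGORITHMS",
    "Agent",
    "OptimizerRun",
    "NonFiniteFitnessError",
    "minimize",
    "default_config",
    "IwoConfig",
    "TlboConfig",
    "LcoConfig",
    "BasConfig",
    "CsoConfig",
    "FfoConfig",
    "iwo_seed_count",
    "iwo_sigma",
    "iwo_step",
    "tlbo_teaching_factor",
    "tlbo_step",
    "lco_schedule",
    "lco_win_probability",
    "lco_play_match",
    "lco_step",
    "bas_decay",
    "bas_step",
    "cso_step",
    "ffo_step",
    "smell_concentration",
]

ALGORITHMS = {
    "iwo": (iwo.run, IwoConfig),
    "tlbo": (tlbo.run, TlboConfig),
    "lco": (lco.run, LcoConfig),
    "baso": (bas.run, BasConfig),
    "cso": (cso.run, CsoConfig),
    "ffo": (ffo.run, FfoConfig),
}


def default_config(algorithm: str):
    """A fresh default configuration object for the named algorithm."""
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    return ALGORITHMS[algorithm][1]()


def minimize(
    algorithm: str,
    fitness,
    d: int,
    config=None,
    seed: int = 0,
    bounds: tuple[float, float] = (0.0, 1.0),
    max_evals: int | None = None,
) -> OptimizerRun:
    """Minimize a black-box fitness over ``[lo, hi]^d``.

    ``config`` defaults to the algorithm's standard configuration;
    ``max_evals`` hard-caps fitness evaluations (the run stops cleanly
    when the budget is spent).  Identical arguments reproduce identical
    runs.
    """
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    runner, config_cls = ALGORITHMS[algorithm]
    if config is None:
        config = config_cls()
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    tracker = Tracker(fitness, lo, hi, max_evals=max_evals)
    rng = np.random.default_rng(seed)
    try:
        runner(tracker, d, config, rng)
    except BudgetExhausted:
        pass
    if not tracker.trace or tracker.trace[-1] != tracker.best_fitness:
        tracker.end_iteration()
    if tracker.best_position is None:
        raise RuntimeError("optimizer finished without a single recorded evaluation")
    return OptimizerRun(
        best_position=tracker.best_position,
        best_fitness=tracker.best_fitness,
        trace=tracker.trace,
        evaluations=tracker.evaluations,
        seed=seed,
    )
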