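"""Level-2 wrapper selection: optimizer positions decode to gene subsets.

A candidate solution is a real vector over the filtered gene pool (the
MRMR top-K, default 600); the decoded subset is the set of the k largest
coordinates, which guarantees the fixed subset sizes (30/60/90 by
default) by construction.  The wrapper fitness is one minus the
cross-validated accuracy fraction of the chosen classifier on the
subset's columns, with folds fixed by a seed so fitness is
deterministic per (subset, seed); lower is better.  Identical decoded
subsets are cached within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datagen import ExpressionDataset
from .evaluation import CLASSIFIERS, cross_val_confusion
from .metaheuristics import OptimizerRun, minimize
from .mrmr import GeneRanking

__all__ = [
    "SelectionProblem",
    "SelectionResult",
    "decode_position",
    "subset_fitness",
    "select_genes",
]


@dataclass(frozen=True)
class SelectionProblem:
    """Wrapper-selection settings for one cell of the pipeline grid."""

    k: int = 30
    classifier: str = "QDA"
    cv_folds: int = 10
    fitness_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; choose from {CLASSIFIERS}"
            )


@dataclass
class SelectionResult:
    """The selected subset (dataset gene indices), its recomputed wrapper
    fitness, and the optimizer run that produced it."""

    genes: np.ndarray
    fitness: float
    optimizer_run: OptimizerRun = field(repr=False)


def decode_position(position: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` largest coordinates, ascending; ties break
    toward the lower index.  Deterministic."""
    position = np.asarray(position, dtype=float)
    if not (1 <= k <= position.size):
        raise ValueError(f"k must be in [1, {position.size}], got {k}")
    order = np.argsort(-position, kind="stable")
    return np.sort(order[:k])


def subset_fitness(
    genes: np.ndarray,
    dataset: ExpressionDataset,
    problem: SelectionProblem,
    sample_indices: np.ndarray | None = None,
) -> float:
    """1 - cross-validated accuracy fraction of the subset; lower is better."""
    counts = cross_val_confusion(
        dataset,
        genes,
        problem.classifier,
        k_folds=problem.cv_folds,
        seed=problem.fitness_seed,
        sample_indices=sample_indices,
    )
    return 1.0 - (counts.tp + counts.tn) / counts.total


def select_genes(
    dataset: ExpressionDataset,
    ranking: GeneRanking,
    problem: SelectionProblem,
    algorithm: str,
    config=None,
    seed: int = 0,
    pool_size: int | None = None,
    max_evals: int | None = None,
    sample_indices: np.ndarray | None = None,
) -> SelectionResult:
    """Run the chosen optimizer over positions on the ranked pool.

    The reported fitness is recomputed from scratch on the returned
    subset (never read from the cache), and the whole procedure is
    reproducible from ``seed``.
    """
    pool = np.asarray(ranking.order[: pool_size or len(ranking.order)], dtype=int)
    if problem.k > pool.size:
        raise ValueError(
            f"k ({problem.k}) exceeds the candidate pool size ({pool.size})"
        )
    cache: dict[tuple[int, ...], float] = {}

    def fitness(position: np.ndarray) -> float:
        local = decode_position(position, problem.k)
        key = tuple(local.tolist())
        if key not in cache:
            cache[key] = subset_fitness(pool[local], dataset, problem, sample_indices)
        return cache[key]

    run = minimize(
        algorithm,
        fitness,
        d=pool.size,
        config=config,
        seed=seed,
        bounds=(0.0, 1.0),
        max_evals=max_evals,
    )
    genes = pool[decode_position(run.best_position, problem.k)]
    final = subset_fitness(genes, dataset, problem, sample_indices)
    return SelectionResult(genes=genes, fitness=final, optimizer_run=run)
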