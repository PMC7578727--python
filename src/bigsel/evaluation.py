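"""Cross-validated classification and the PC/MC/FA metric suite.

Predictions are pooled over stratified 10-fold cross-validation into one
confusion table with the tumour class (label 1) positive, then expressed
as percentages of evaluated samples:

    PC (perfect classification) = 100 (TP + TN) / n
    MC (missed classification)  = 100 FN / n      (tumours called healthy)
    FA (false alarm)            = 100 FP / n      (healthy called tumour)

so PC + MC + FA = 100.  Five derived statistics follow:

    Sensitivity = 100 PC / (PC + FA)
    Specificity = 100 PC / (PC + MC)
    Accuracy    = (Sensitivity + Specificity) / 2
    PI          = 100 (PC - MC - FA) / PC      (may be negative)
    GDR         = 100 (PC - MC) / (PC + FA)

Classifiers are thin adapters over scikit-learn with pinned defaults:
random forest (100 trees), AdaBoost (50 stumps), logistic regression
(lbfgs, max_iter=1000), CART decision tree, and QDA (refit with
reg_param=1e-3 if the class covariances are singular).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .datagen import TUMOR_LABEL, ExpressionDataset

CLASSIFIERS = ("RF", "Adaboost", "LR", "DT", "QDA")

__all__ = [
    "CLASSIFIERS",
    "ConfusionCounts",
    "MetricsReport",
    "MetricsUndefinedError",
    "stratified_folds",
    "train_predict",
    "cross_val_confusion",
    "confusion_to_pc_mc_fa",
    "compute_metrics",
    "evaluate_subset",
    "grid_report",
    "GridReport",
    "derive_cell_seed",
]


class MetricsUndefinedError(ValueError):
    """PI is undefined when PC = 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled out-of-fold confusion counts; positive class = tumour."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """PC/MC/FA percentages plus the five derived statistics."""

    pc: float
    mc: float
    fa: float
    sensitivity: float
    specificity: float
    accuracy: float
    pi: float
    gdr: float


def stratified_folds(
    labels: np.ndarray, k_folds: int, seed: int = 0
) -> list[np.ndarray]:
    """Seeded stratified partition into ``k_folds`` disjoint test sets."""
    labels = np.asarray(labels)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > labels.size:
        raise ValueError(
            f"k_folds ({k_folds}) exceeds the number of samples ({labels.size})"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((labels.size, 1)), labels)]


def _build_classifier(kind: str, seed: int):
    if kind == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "Adaboost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if kind == "LR":
        return LogisticRegression(max_iter=1000)
    if kind == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "QDA":
        return QuadraticDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {kind!r}; choose from {CLASSIFIERS}")


def train_predict(
    classifier_kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit the named classifier and predict test labels.

    QDA falls back to Ledoit-Wolf-shrunk class covariances (eigen
    solver, shrinkage="auto") whenever a within-class covariance is
    rank deficient, e.g. when a class has fewer samples than the subset
    has genes.
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training data must contain both classes")
    clf = _build_classifier(classifier_kind, seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            clf.fit(X_train, y_train)
        except np.linalg.LinAlgError:
            if classifier_kind != "QDA":
                raise
            clf = QuadraticDiscriminantAnalysis(solver="eigen", shrinkage="auto")
            clf.fit(X_train, y_train)
        return clf.predict(X_test)


def cross_val_confusion(
    dataset: ExpressionDataset,
    genes: np.ndarray,
    classifier_kind: str,
    k_folds: int = 10,
    seed: int = 0,
    sample_indices: np.ndarray | None = None,
) -> ConfusionCounts:
    """Pooled out-of-fold confusion counts on the restricted gene columns."""
    genes = np.asarray(genes, dtype=int)
    if genes.size == 0:
        raise ValueError("empty gene subset")
    if np.unique(genes).size != genes.size:
        raise ValueError("duplicate gene indices in subset")
    if genes.min() < 0 or genes.max() >= dataset.n_genes:
        raise ValueError("gene index out of range")
    X = dataset.matrix[:, genes]
    y = dataset.labels
    if sample_indices is not None:
        idx = np.asarray(sample_indices, dtype=int)
        X, y = X[idx], y[idx]
    tp = tn = fp = fn = 0
    for fold_no, test_idx in enumerate(stratified_folds(y, k_folds, seed)):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        if np.unique(y[test_idx]).size < 2 and y.size >= 2 * k_folds:
            # stratification should prevent this; guard for tiny inputs
            raise ValueError(f"fold {fold_no} contains a single class")
        pred = train_predict(
            classifier_kind, X[train_idx], y[train_idx], X[test_idx], seed
        )
        truth = y[test_idx]
        tp += int(np.sum((truth == TUMOR_LABEL) & (pred == TUMOR_LABEL)))
        tn += int(np.sum((truth != TUMOR_LABEL) & (pred != TUMOR_LABEL)))
        fp += int(np.sum((truth != TUMOR_LABEL) & (pred == TUMOR_LABEL)))
        fn += int(np.sum((truth == TUMOR_LABEL) & (pred != TUMOR_LABEL)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion_to_pc_mc_fa(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Percentage decomposition (PC, MC, FA) of the confusion counts."""
    n = counts.total
    if n == 0:
        raise ValueError("no evaluated samples")
    return (
        100.0 * (counts.tp + counts.tn) / n,
        100.0 * counts.fn / n,
        100.0 * counts.fp / n,
    )


def compute_metrics(pc: float, mc: float, fa: float) -> MetricsReport:
    """Derive the five statistics from the PC/MC/FA decomposition."""
    if abs(pc + mc + fa - 100.0) > 1e-6:
        raise ValueError(f"PC + MC + FA must equal 100, got {pc + mc + fa}")
    if pc == 0:
        raise MetricsUndefinedError("PI is undefined when PC = 0")
    sensitivity = 100.0 * pc / (pc + fa)
    specificity = 100.0 * pc / (pc + mc)
    accuracy = (sensitivity + specificity) / 2.0
    pi = 100.0 * (pc - mc - fa) / pc
    gdr = 100.0 * (pc - mc) / (pc + fa)
    return MetricsReport(
        pc=pc,
        mc=mc,
        fa=fa,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        pi=pi,
        gdr=gdr,
    )


def evaluate_subset(
    dataset: ExpressionDataset,
    genes: np.ndarray,
    classifier_kind: str,
    k_folds: int = 10,
    seed: int = 0,
    sample_indices: np.ndarray | None = None,
) -> MetricsReport:
    """Pooled 10-fold cross-validated metrics for one gene subset."""
    counts = cross_val_confusion(
        dataset, genes, classifier_kind, k_folds, seed, sample_indices
    )
    return compute_metrics(*confusion_to_pc_mc_fa(counts))


def derive_cell_seed(master_seed: int, algorithm: str, classifier: str, k: int) -> int:
    """Deterministic per-cell seed from the master seed and cell coordinates."""
    key = f"{master_seed}|{algorithm}|{classifier}|{k}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class GridReport:
    """Per-cell metric reports over (classifier, k) x algorithm, plus the
    column averages and the per-(classifier, k) cross-algorithm means."""

    cells: dict[tuple[str, str, int], MetricsReport | None]
    errors: dict[tuple[str, str, int], str]
    algorithms: list[str]
    classifiers: list[str]
    k_values: list[int]
    seeds: dict[tuple[str, str, int], int]
    selected_genes: dict[tuple[str, str, int], list[int]]

    _METRICS = ("accuracy", "pc", "mc", "fa", "sensitivity", "specificity", "pi", "gdr")

    def metric_table(self, metric: str) -> pd.DataFrame:
        """Rows = classifier x k, columns = algorithm, plus an Average row."""
        rows = []
        index = []
        for clf in self.classifiers:
            for k in self.k_values:
                index.append(f"{clf}/{k}")
                rows.append(
                    [
                        getattr(self.cells.get((alg, clf, k)), metric, np.nan)
                        if self.cells.get((alg, clf, k)) is not None
                        else np.nan
                        for alg in self.algorithms
                    ]
                )
        df = pd.DataFrame(rows, index=index, columns=self.algorithms, dtype=float)
        df.loc["Average"] = df.mean(axis=0)
        return df

    def classifier_averages(self) -> pd.DataFrame:
        """Cross-algorithm mean of accuracy/PC/PI/GDR per (classifier, k)."""
        rows = []
        index = []
        for clf in self.classifiers:
            for k in self.k_values:
                index.append(f"{clf}/{k}")
                vals = [
                    self.cells.get((alg, clf, k))
                    for alg in self.algorithms
                    if self.cells.get((alg, clf, k)) is not None
                ]
                rows.append(
                    [
                        float(np.mean([getattr(v, m) for v in vals])) if vals else np.nan
                        for m in ("accuracy", "pc", "pi", "gdr")
                    ]
                )
        return pd.DataFrame(
            rows, index=index, columns=["accuracy", "pc", "pi", "gdr"], dtype=float
        )

    def to_json_dict(self) -> dict:
        return {
            "algorithms": self.algorithms,
            "classifiers": self.classifiers,
            "k_values": self.k_values,
            "cells": {
                f"{alg}|{clf}|{k}": (asdict(rep) if rep is not None else None)
                for (alg, clf, k), rep in sorted(self.cells.items())
            },
            "errors": {f"{a}|{c}|{k}": e for (a, c, k), e in sorted(self.errors.items())},
            "seeds": {f"{a}|{c}|{k}": s for (a, c, k), s in sorted(self.seeds.items())},
            "selected_genes": {
                f"{a}|{c}|{k}": g for (a, c, k), g in sorted(self.selected_genes.items())
            },
            "tables": {
                m: json.loads(self.metric_table(m).to_json(orient="index"))
                for m in self._METRICS
            },
            "classifier_averages": json.loads(
                self.classifier_averages().to_json(orient="index")
            ),
        }


def grid_report(
    dataset: ExpressionDataset,
    ranking,
    k_values: list[int],
    algorithms: list[str],
    classifiers: list[str],
    configs: dict | None = None,
    seed: int = 0,
    pool_size: int | None = None,
    cv_folds: int = 10,
    max_evals: int | None = None,
) -> GridReport:
    """Run selection + evaluation for every (algorithm, classifier, k) cell.

    Failed cells are recorded with their error message and the run
    continues; an exception is raised only if every cell fails.
    """
    from .subset_selection import SelectionProblem, select_genes

    configs = configs or {}
    cells: dict[tuple[str, str, int], MetricsReport | None] = {}
    errors: dict[tuple[str, str, int], str] = {}
    seeds: dict[tuple[str, str, int], int] = {}
    genes_out: dict[tuple[str, str, int], list[int]] = {}
    for alg in algorithms:
        for clf in classifiers:
            for k in k_values:
                cell_seed = derive_cell_seed(seed, alg, clf, k)
                seeds[(alg, clf, k)] = cell_seed
                try:
                    problem = SelectionProblem(
                        k=k, classifier=clf, cv_folds=cv_folds, fitness_seed=cell_seed
                    )
                    result = select_genes(
                        dataset,
                        ranking,
                        problem,
                        alg,
                        config=configs.get(alg),
                        seed=cell_seed,
                        pool_size=pool_size,
                        max_evals=max_evals,
                    )
                    report = evaluate_subset(
                        dataset, result.genes, clf, cv_folds, cell_seed
                    )
                    cells[(alg, clf, k)] = report
                    genes_out[(alg, clf, k)] = [int(g) for g in result.genes]
                except Exception as exc:  # isolate per-cell failures
                    cells[(alg, clf, k)] = None
                    errors[(alg, clf, k)] = f"{type(exc).__name__}: {exc}"
    if cells and all(v is None for v in cells.values()):
        raise RuntimeError(f"all cells failed: {errors}")
    return GridReport(
        cells=cells,
        errors=errors,
        algorithms=list(algorithms),
        classifiers=list(classifiers),
        k_values=list(k_values),
        seeds=seeds,
        selected_genes=genes_out,
    )
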