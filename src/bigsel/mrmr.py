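"""Minimum-redundancy maximum-relevance (MRMR) gene ranking.

Level-1 filter of the bilevel pipeline.  Relevance T of a gene set is the
mean mutual information (MI, in bits) between each gene and the class
label; redundancy R is the mean pairwise MI over the set, self-terms
included.  For continuous-mode scoring the one-way ANOVA F statistic
replaces MI on the relevance side and mean absolute Pearson correlation
replaces it on the redundancy side.  Ranking uses greedy forward
selection with the difference criterion (MID): the next gene maximizes
relevance(g) minus its mean redundancy against the genes already picked.

MI needs discrete inputs, so expression values are binned per gene
(equal-frequency, 3 bins by default — the de-facto MRMR convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datagen import ExpressionDataset

__all__ = [
    "DiscretizedMatrix",
    "GeneRanking",
    "discretize",
    "mutual_information",
    "relevance",
    "redundancy",
    "f_statistic",
    "correlation_redundancy",
    "mrmr_select",
]


@dataclass
class DiscretizedMatrix:
    """Per-gene independently binned codes in ``[0, n_bins)``."""

    codes: np.ndarray
    n_bins: int
    bin_edges: list[np.ndarray]


def discretize(
    matrix: np.ndarray, n_bins: int = 3, strategy: str = "equal-frequency"
) -> DiscretizedMatrix:
    """Bin each gene independently; constant genes map to a single code."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if strategy not in ("equal-width", "equal-frequency"):
        raise ValueError(f"unknown strategy {strategy!r}")
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    codes = np.zeros(X.shape, dtype=np.int64)
    edges_out: list[np.ndarray] = []
    for j in range(X.shape[1]):
        x = X[:, j]
        lo, hi = x.min(), x.max()
        if lo == hi:
            edges_out.append(np.array([lo, hi]))
            continue
        if strategy == "equal-width":
            edges = np.linspace(lo, hi, n_bins + 1)
            # left-closed bins: a value on an interior edge joins the upper bin
            codes[:, j] = np.searchsorted(edges[1:-1], x, side="right")
        else:
            qs = np.linspace(0, 1, n_bins + 1)
            interior = np.unique(np.quantile(x, qs[1:-1]))
            # side="left" keeps quantile-tied values in the lower bin, so
            # heavily tied (e.g. binary-valued) genes never collapse to one code
            codes[:, j] = np.searchsorted(interior, x, side="left")
            edges = np.concatenate([[lo], interior, [hi]])
        edges_out.append(edges)
    return DiscretizedMatrix(codes=codes, n_bins=n_bins, bin_edges=edges_out)


def _as_codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    _, inv = np.unique(np.asarray(v), return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI estimate in bits from the empirical joint distribution."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("empty vectors")
    xi, kx = _as_codes(x)
    yi, ky = _as_codes(y)
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _mi_vector_vs_columns(v_codes: np.ndarray, kv: int, codes: np.ndarray, kc: int) -> np.ndarray:
    """MI (bits) of one discrete vector against every column of ``codes``."""
    n, g = codes.shape
    counts = np.zeros((kv, kc, g))
    for a in range(kv):
        block = codes[v_codes == a]
        for b in range(kc):
            counts[a, b] = (block == b).sum(axis=0)
    p = counts / n
    pv = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pv * pc))
    return np.nansum(terms, axis=(0, 1))


def relevance(genes: DiscretizedMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Mean MI between each gene in the set and the class label (T)."""
    codes = genes.codes if isinstance(genes, DiscretizedMatrix) else np.atleast_2d(genes)
    if codes.shape[1] == 0:
        raise ValueError("empty gene set")
    return float(
        np.mean([mutual_information(codes[:, j], labels) for j in range(codes.shape[1])])
    )


def redundancy(genes: DiscretizedMatrix | np.ndarray) -> float:
    """Mean pairwise MI over the set, self-terms (i = j) included (R)."""
    codes = genes.codes if isinstance(genes, DiscretizedMatrix) else np.atleast_2d(genes)
    m = codes.shape[1]
    if m == 0:
        raise ValueError("empty gene set")
    total = 0.0
    for i in range(m):
        for j in range(m):
            total += mutual_information(codes[:, i], codes[:, j])
    return total / (m * m)


def f_statistic(gene: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F between the two classes.

    Zero within-class variance with unequal class means is signalled as
    ``inf`` (an absorbing-max relevance score).
    """
    gene = np.asarray(gene, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    a = gene[labels == classes[0]]
    b = gene[labels == classes[1]]
    if a.size < 1 or b.size < 1:
        raise ValueError("each class needs at least one sample")
    grand = gene.mean()
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ssw == 0.0:
        return math.inf if a.mean() != b.mean() else 0.0
    return float(ssb / (ssw / (gene.size - 2)))


def correlation_redundancy(genes: np.ndarray) -> float:
    """Mean absolute pairwise Pearson correlation, self-terms included.

    Constant genes contribute correlation 0 everywhere (including their
    own self-term) by convention.
    """
    X = np.atleast_2d(np.asarray(genes, dtype=float))
    m = X.shape[1]
    if m == 0:
        raise ValueError("empty gene set")
    sd = X.std(axis=0)
    ok = sd > 0
    C = np.zeros((m, m))
    if ok.any():
        sub = np.atleast_2d(np.corrcoef(X[:, ok], rowvar=False))
        C[np.ix_(ok, ok)] = np.abs(sub)
    return float(C.sum() / (m * m))


@dataclass
class GeneRanking:
    """Greedy MRMR ranking: selection order plus per-pick diagnostics.

    ``relevance[r]`` is the relevance score of the gene picked at rank r;
    ``redundancy_at_selection[r]`` its mean redundancy against the genes
    already selected at that point (0 for the first pick).
    """

    order: list[int]
    relevance: np.ndarray
    redundancy_at_selection: np.ndarray
    mode: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking order contains duplicate genes")


def _abs_corr_vs_columns(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    sv = v.std()
    sx = X.std(axis=0)
    if sv == 0:
        return np.zeros(X.shape[1])
    cov = (X - X.mean(axis=0)).T @ (v - v.mean()) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sv * sx)
    r[sx == 0] = 0.0
    return np.abs(r)


def mrmr_select(
    dataset: ExpressionDataset,
    k: int,
    mode: str = "mi",
    n_bins: int = 3,
    strategy: str = "equal-frequency",
    combination: str = "difference",
    sample_indices: np.ndarray | None = None,
) -> GeneRanking:
    """Greedy forward MRMR selection of ``k`` genes.

    ``mode='mi'`` scores relevance and redundancy by mutual information
    on discretized data; ``mode='f'`` uses the ANOVA F statistic and
    absolute correlation on the raw values.  ``combination`` picks the
    difference (MID, default) or quotient (MIQ) rule.  Ties break toward
    the lower gene index.  Deterministic given its inputs.
    """
    X = dataset.matrix
    y = dataset.labels
    if sample_indices is not None:
        idx = np.asarray(sample_indices, dtype=int)
        X, y = X[idx], y[idx]
    g = X.shape[1]
    if not (1 <= k <= g):
        raise ValueError(f"k must be in [1, {g}], got {k}")
    if mode not in ("mi", "f"):
        raise ValueError(f"unknown mode {mode!r}")
    if combination not in ("difference", "quotient"):
        raise ValueError(f"unknown combination {combination!r}")

    y_codes, ky = _as_codes(y)
    if mode == "mi":
        disc = discretize(X, n_bins=n_bins, strategy=strategy)
        codes = disc.codes
        rel = _mi_vector_vs_columns(y_codes, ky, codes, n_bins)
    else:
        rel = np.array([f_statistic(X[:, j], y) for j in range(g)])

    order: list[int] = []
    rel_out: list[float] = []
    red_out: list[float] = []
    red_sum = np.zeros(g)
    selected = np.zeros(g, dtype=bool)

    first = int(np.argmax(rel))
    order.append(first)
    rel_out.append(float(rel[first]))
    red_out.append(0.0)
    selected[first] = True

    for _ in range(1, k):
        last = order[-1]
        if mode == "mi":
            last_codes, klast = _as_codes(codes[:, last])
            red_sum += _mi_vector_vs_columns(last_codes, klast, codes, n_bins)
        else:
            red_sum += _abs_corr_vs_columns(X[:, last], X)
        mean_red = red_sum / len(order)
        if combination == "difference":
            score = rel - mean_red
        else:
            score = rel / (mean_red + 1e-12)
        score[selected] = -np.inf
        nxt = int(np.argmax(score))
        order.append(nxt)
        rel_out.append(float(rel[nxt]))
        red_out.append(float(mean_red[nxt]))
        selected[nxt] = True

    return GeneRanking(
        order=order,
        relevance=np.array(rel_out),
        redundancy_at_selection=np.array(red_out),
        mode={"mi": f"MI-{combination}", "f": "F-correlation"}[mode],
        gene_ids=[dataset.gene_ids[j] for j in order],
    )
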