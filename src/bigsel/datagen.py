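"""Expression-matrix I/O and synthetic two-class microarray data.

The synthetic generator emulates the shape of a classic two-class colon
tumour microarray study: ~62 samples by ~2000 genes, unbalanced classes
(40 tumour / 22 healthy), with a small planted set of class-informative
genes on an i.i.d. Gaussian noise background.  Labels follow the 1/2
convention with class 1 = tumour (the positive class downstream).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR_LABEL = 1
HEALTHY_LABEL = 2

__all__ = [
    "TUMOR_LABEL",
    "HEALTHY_LABEL",
    "ExpressionDataset",
    "SyntheticSpec",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]


@dataclass
class ExpressionDataset:
    """A samples x genes real matrix with two-class labels.

    Invariants checked at construction: matrix row count equals label
    count, no missing values, exactly two distinct label values, unique
    gene identifiers.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be two-dimensional (samples x genes)")
        n, g = self.matrix.shape
        if not self.gene_ids:
            self.gene_ids = [f"G{j + 1:04d}" for j in range(g)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        if self.labels.shape != (n,):
            raise ValueError(
                f"label count ({self.labels.size}) must equal matrix row count ({n})"
            )
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length must equal matrix column count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal matrix row count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains missing or non-finite values")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if np.unique(self.labels).size != 2:
            raise ValueError(
                "exactly two distinct label values required, got "
                f"{np.unique(self.labels).tolist()}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def restricted(self, sample_indices: np.ndarray) -> "ExpressionDataset":
        """Sub-dataset over a set of sample rows (used for nested protocols)."""
        idx = np.asarray(sample_indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal generative model.

    Informative genes are shifted by ``effect_size * noise_sd`` in the
    tumour class; every other gene is class-independent Gaussian noise.
    """

    n_samples: int = 62
    n_genes: int = 2000
    n_informative: int = 20
    class_sizes: tuple[int, int] = (40, 22)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError(
                f"n_informative ({self.n_informative}) must be <= n_genes ({self.n_genes})"
            )
        if len(self.class_sizes) != 2 or min(self.class_sizes) < 1:
            raise ValueError("class_sizes must be two positive integers")
        if sum(self.class_sizes) != self.n_samples:
            raise ValueError(
                f"class_sizes {self.class_sizes} must sum to n_samples ({self.n_samples})"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Draw a dataset from the planted-signal model.

    Returns the dataset and the sorted indices of the planted informative
    genes (the ground truth for recovery experiments).  Identical specs
    (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    matrix = rng.normal(0.0, spec.noise_sd, size=(n, g))
    planted = np.sort(rng.choice(g, size=spec.n_informative, replace=False))
    n_tumor, n_healthy = spec.class_sizes
    labels = np.concatenate(
        [np.full(n_tumor, TUMOR_LABEL), np.full(n_healthy, HEALTHY_LABEL)]
    )
    if spec.n_informative:
        shift = spec.effect_size * spec.noise_sd
        matrix[np.ix_(np.flatnonzero(labels == TUMOR_LABEL), planted)] += shift
    dataset = ExpressionDataset(matrix=matrix, labels=labels)
    return dataset, planted


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_dataset(
    path: str,
    label_col: str = "label",
    labels_path: str | None = None,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ExpressionDataset:
    """Parse a delimited expression matrix (rows = samples by default).

    Labels come either from a ``label_col`` column of the matrix file or
    from a separate one-column file.  With ``transpose=True`` the file is
    read as genes-as-rows (first column gene ids, header = sample ids)
    and labels must be supplied via ``labels_path``.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    if transpose:
        gene_ids = df.iloc[:, 0].tolist()
        sample_ids = list(df.columns[1:])
        values = df.iloc[:, 1:]
        if labels_path is None:
            raise ValueError("transpose=True requires labels_path")
        labels = None
    else:
        first = df.columns[0]
        if first.lower() in ("sample_id", "sample", "id"):
            sample_ids = df[first].tolist()
            df = df.drop(columns=[first])
        else:
            sample_ids = [f"S{i + 1:03d}" for i in range(len(df))]
        labels = None
        if labels_path is None:
            if label_col not in df.columns:
                raise ValueError(
                    f"{path}: missing labels — no column named {label_col!r} "
                    "and no separate label file given"
                )
            labels = pd.to_numeric(df[label_col], errors="raise").to_numpy(dtype=int)
            df = df.drop(columns=[label_col])
        gene_ids = list(df.columns)
        values = df

    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() & values.notna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric value {values.iat[r, c]!r} at row {r + 1}, column {c + 1}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {r + 1}, column {c + 1}")

    # numpy's string->float conversion is correctly rounded (pandas' fast
    # parser is not), which keeps write -> read round trips bit-exact
    matrix = values.to_numpy().astype(np.float64)
    if transpose:
        matrix = matrix.T

    if labels is None:
        lab = pd.read_csv(labels_path, header=None).iloc[:, 0]
        labels = pd.to_numeric(lab, errors="raise").to_numpy(dtype=int)

    return ExpressionDataset(
        matrix=matrix, labels=labels, gene_ids=gene_ids, sample_ids=sample_ids
    )


def write_dataset(dataset: ExpressionDataset, path: str, delimiter: str = ",") -> None:
    """Write a dataset as delimited text readable by :func:`read_dataset`.

    Floats are printed with 17 significant digits so a read/write round
    trip is bit-exact.
    """
    if dataset.n_samples == 0 or dataset.n_genes == 0:
        raise ValueError("refusing to write an empty dataset")
    df = pd.DataFrame(dataset.matrix, columns=dataset.gene_ids)
    df.insert(0, "sample_id", dataset.sample_ids)
    df["label"] = dataset.labels
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
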