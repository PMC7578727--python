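import numpy as np
import pytest

from bigsel import ExpressionDataset, SyntheticSpec, generate_dataset
from bigsel.mrmr import GeneRanking


def make_planted(
    n_genes=200,
    n_informative=10,
    effect=2.5,
    seed=42,
    n_samples=62,
    class_sizes=(40, 22),
):
    spec = SyntheticSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        n_informative=n_informative,
        class_sizes=class_sizes,
        effect_size=effect,
        noise_sd=1.0,
        seed=seed,
    )
    return generate_dataset(spec)


def identity_ranking(n_genes):
    """A pass-through pool over all genes, for tests that bypass MRMR."""
    return GeneRanking(
        order=list(range(n_genes)),
        relevance=np.zeros(n_genes),
        redundancy_at_selection=np.zeros(n_genes),
        mode="identity",
    )


def permute_labels(dataset, seed):
    rng = np.random.default_rng(seed)
    return ExpressionDataset(
        matrix=dataset.matrix,
        labels=rng.permutation(dataset.labels),
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
    )


@pytest.fixture(scope="session")
def strong_fixture():
    """62 x 200 planted-signal dataset: 10 informative genes, effect 2.5."""
    return make_planted(seed=42)
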