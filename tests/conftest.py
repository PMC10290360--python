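import numpy as np
import pytest

from scnoise.counts import CountMatrix


def make_cm(counts, gene_prefix="g", cell_prefix="c"):
    counts = np.asarray(counts)
    return CountMatrix(
        counts,
        gene_ids=np.array([f"{gene_prefix}{i}" for i in range(counts.shape[0])], dtype=object),
        cell_ids=np.array([f"{cell_prefix}{j}" for j in range(counts.shape[1])], dtype=object),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def nb_counts():
    """NB counts with depth-proportional means, theta=2; genes x cells."""
    rng = np.random.default_rng(7)
    n_genes, n_cells = 80, 400
    depth = rng.gamma(5.0, 2000.0 / 5.0, size=n_cells)
    frac = rng.dirichlet(np.ones(n_genes) * 2.0)
    theta = 2.0
    mu = frac[:, None] * depth[None, :]
    X = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)
    return make_cm(X)
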