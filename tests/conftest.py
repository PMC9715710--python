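import numpy as np
import pandas as pd
import pytest
from anndata import AnnData


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_adata(X, ds_id="x", cell_types=None, gene_prefix="g"):
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    obs = pd.DataFrame(index=[f"{ds_id}{i}" for i in range(n)])
    obs["dataset_id"] = ds_id
    if cell_types is not None:
        obs["cell_type"] = cell_types
    var = pd.DataFrame(index=[f"{gene_prefix}{j:03d}" for j in range(p)])
    return AnnData(X=X, obs=obs, var=var)


@pytest.fixture
def toy_counts(rng):
    """A small random count matrix with heterogeneous gene means."""
    means = rng.uniform(0.5, 20, size=30)
    return make_adata(rng.poisson(means, size=(40, 30)))


@pytest.fixture(scope="session")
def tiny_partition():
    """A small preprocessed two-dataset partition for fast training tests."""
    from otvae.preprocess import preprocess_pair
    from otvae.synthdata import SimConfig, simulate

    ax, ay, _ = simulate(SimConfig(n_cells=80, n_common_genes=40,
                                   n_specific_genes=20, seed=7))
    return preprocess_pair(ax, ay, min_genes_per_cell=1, min_cells_per_gene=1)


def tiny_train_config(**overrides):
    from otvae.train import TrainConfig

    kw = dict(batch_size=32, max_iterations=60, hidden_dims=(32, 16),
              latent_dim=8, patience=1000, seed=0)
    kw.update(overrides)
    return TrainConfig(**kw)
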