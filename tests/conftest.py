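import dataclasses

import numpy as np
import pytest

import glycopred as gp
from glycopred.preprocess import with_split

SMALL = gp.SyntheticConfig(
    n_cells=700,
    n_genes=160,
    n_drivers_pos=12,
    n_drivers_neg=4,
    seed=42,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Paired synthetic dataset small enough for fast unit tests."""
    return gp.generate_dataset(SMALL)


@pytest.fixture(scope="session")
def small_labeled(small_dataset):
    expr, lectin, _ = small_dataset
    return with_split(gp.build_labeled_dataset(expr, lectin), seed=5)


@pytest.fixture(scope="session")
def small_model(small_labeled):
    """One classifier trained on the small dataset (120 epochs)."""
    ds = small_labeled
    model = gp.build_mlp(gp.MLPSpec(input_dim=len(ds.gene_ids)), seed=1)
    model, history = gp.train_mlp(
        model,
        *ds.subset("train"),
        *ds.subset("validation"),
        gp.TrainConfig(max_epochs=120, seed=7),
    )
    return model, history


@pytest.fixture()
def tiny_net():
    """Untrained 8-input network with random-ish weights for oracle checks."""

    def make(seed: int, input_dim: int = 8) -> gp.MLPClassifier:
        spec = gp.MLPSpec(input_dim=input_dim)
        model = gp.build_mlp(spec, seed=seed)
        rng = np.random.default_rng(seed + 1)
        # perturb batch-norm buffers so the folded affine transform is nontrivial
        for i in range(3):
            model.running_mean[i] = rng.normal(0, 0.3, model.running_mean[i].shape)
            model.running_var[i] = np.exp(rng.normal(0, 0.3, model.running_var[i].shape))
            model.gamma[i] = np.exp(rng.normal(0, 0.2, model.gamma[i].shape))
            model.beta[i] = rng.normal(0, 0.2, model.beta[i].shape)
        return model

    return make


def small_config(**overrides) -> gp.SyntheticConfig:
    return dataclasses.replace(SMALL, **overrides)
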