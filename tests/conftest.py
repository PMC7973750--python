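import numpy as np
import pytest

from omicsvae import io, models
from omicsvae.synthetic import (BlockSpec, SurvivalSpec, SyntheticSpec,
                                generate_multiomics)


@pytest.fixture(scope="session")
def small_spec():
    """A compact 3-block cohort with planted classes and survival."""
    coefs = np.zeros(6)
    coefs[0] = 1.0
    return SyntheticSpec(
        n_samples=120, latent_dim_true=6, n_classes=4,
        class_proportions=(0.25,) * 4,
        block_specs=[
            BlockSpec("cnv", 40),
            BlockSpec("mrna", 40),
            BlockSpec("methylation", 40, n_chromosomes=4),
        ],
        class_separation=4.0,
        survival=SurvivalSpec(hazard_coefficients=coefs, censoring_rate=0.3),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    dataset, truth = generate_multiomics(small_spec)
    return dataset, truth


@pytest.fixture(scope="session")
def normalized_dataset(small_dataset):
    dataset, truth = small_dataset
    blocks = [io.minmax_normalize(b) for b in dataset.blocks]
    ds = io.MultiOmicsDataset(blocks, labels=dataset.labels,
                              clinical=dataset.clinical)
    return ds, truth


@pytest.fixture(scope="session")
def tiny_schemas():
    """10 total input features: 6 cnv + 4 methylation over 2 chromosomes."""
    return [
        models.BlockSchema("cnv", 6),
        models.BlockSchema("methylation", 4, [("chr1", [0, 1]), ("chr2", [2, 3])]),
    ]


@pytest.fixture(scope="session")
def tiny_inputs():
    rng = np.random.default_rng(0)
    return [rng.uniform(0.05, 0.95, (12, 6)), rng.uniform(0.05, 0.95, (12, 4))]


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_schemas, tiny_inputs):
    """A small supervised ELBO model trained for a handful of epochs."""
    spec = models.ModelSpec(
        latent_dim=3, hidden_widths=(8, 6), chromosome_width=4, fused_width=5,
        loss_kind="elbo", beta=1.0, n_classes=2, epochs=5, batch_size=6,
        seed=3, early_stopping_patience=None)
    model = models.build_model(spec, tiny_schemas)
    labels = np.tile([0, 1], 6)
    models.train(model, tiny_inputs, labels=labels)
    return model
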