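import numpy as np
import pytest

import hemomil as hm
from hemomil.controls import run_negative_control, run_positive_control


@pytest.fixture(scope="session")
def hierarchy():
    return hm.default_hierarchy()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small well-separated cohort: 64 patients, 40 cells, 16 dims."""
    manifest, bags = hm.generate_cohort(
        64, None, 40, seed=101, embedding_dim=16, separation=5.0
    )
    return manifest, bags


@pytest.fixture(scope="session")
def tiny_config():
    return hm.ModelConfig(
        embedding_dim=16, bag_size=40, latent_dim=32, n_heads=4, n_layers=2, seed=3
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_cohort, tiny_config, hierarchy):
    """Single-model ensemble trained briefly on the tiny cohort."""
    manifest, bags = tiny_cohort
    params = hm.TrainParams(epochs=4, lr=1e-3, batch_size=16, k=1, seed=3)
    return hm.train_ensemble(manifest, bags, tiny_config, params, hierarchy=hierarchy)


@pytest.fixture(scope="session")
def positive_control():
    """The full positive-control study: separation-5 cohort of 400
    patients with 200 cells per bag, 5-fold ensemble, held-out fifth."""
    return run_positive_control(seed=20)


@pytest.fixture(scope="session")
def negative_control():
    """Zero-separation cohort: bags carry no class signal."""
    return run_negative_control(seed=21)
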