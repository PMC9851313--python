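import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from muthene.hetnet import HetNet
from muthene.model import ModelConfig
from muthene.pipeline import TrainConfig
from muthene.synthdata import SynthConfig, as_dataset, generate


def small_model_config(**overrides) -> ModelConfig:
    """Desk-scale architecture used throughout the tests."""
    base = dict(d_prime=16, hidden=16, n_heads=2, d_head=8, d_attn=16,
                d_cell=16, dnn_base_width=128, dnn_depth=2, dropout=0.2)
    base.update(overrides)
    return ModelConfig(**base)


def small_train_config(**overrides) -> TrainConfig:
    base = dict(max_epochs=80, patience=25, batch_size=512, lr=3e-3)
    base.update(overrides)
    return TrainConfig(**base)


def random_hetnet(rng: np.random.Generator, n_drugs=6, n_targets=8,
                  p=0.3) -> HetNet:
    """Independent-edge random heterogeneous network for oracle tests."""
    dti = frozenset((d, t) for d in range(n_drugs) for t in range(n_targets)
                    if rng.random() < p)
    ppi = frozenset(tuple(sorted((a, b)))
                    for a in range(n_targets) for b in range(a + 1, n_targets)
                    if rng.random() < p)
    dd = frozenset(tuple(sorted((a, b)))
                   for a in range(n_drugs) for b in range(a + 1, n_drugs)
                   if rng.random() < p)
    return HetNet(n_drugs=n_drugs, n_targets=n_targets,
                  dti_edges=dti, ppi_edges=ppi, dd_edges=dd)


@pytest.fixture(scope="session")
def synth_default():
    """The default synthetic fixture (20 drugs, 950 triples)."""
    return generate(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def dataset_default(synth_default):
    return as_dataset(synth_default)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, synth_default):
    from muthene.synthdata import write_fixture
    return write_fixture(synth_default, tmp_path_factory.mktemp("fixture"))
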