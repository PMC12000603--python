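import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rxnproto import synthetic
from rxnproto.features import fingerprints as fp


@pytest.fixture(scope="session")
def tiny():
    """30-record synthetic dataset with both classes present."""
    dataset, truth = synthetic.make_fixture("tiny", seed=0)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_dataset(tiny):
    return tiny[0]


@pytest.fixture(scope="session")
def tiny_scaler(tiny_dataset):
    return fp.fit_condition_scaler(tiny_dataset)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_dataset, tiny_scaler):
    return fp.encode_dataset(tiny_dataset, tiny_scaler)


@pytest.fixture(scope="session")
def medium():
    """600-record, 3-cluster dataset for task/episode level tests."""
    dataset, truth = synthetic.generate(
        synthetic.GeneratorConfig(n_records=600, n_clusters=3, seed=7))
    return dataset, truth


@pytest.fixture(scope="session")
def medium_encoded(medium):
    dataset, _ = medium
    scaler = fp.fit_condition_scaler(dataset)
    return dataset, scaler, fp.encode_dataset(dataset, scaler)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
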