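import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dbpred import pipeline
from dbpred.synthetic import SyntheticConfig, generate_dataset, write_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_dataset():
    """20 labelled synthetic proteins with all three track sources."""
    cfg = SyntheticConfig(n_per_class=10, length_range=(40, 220), seed=101)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory, tiny_dataset):
    out = tmp_path_factory.mktemp("synthetic_data")
    write_dataset(tiny_dataset, out)
    return out


@pytest.fixture(scope="session")
def tiny_matrix(tiny_dataset):
    X, schema = pipeline.featurize(tiny_dataset.records, tiny_dataset.track_sets())
    y = pipeline.labels_vector(tiny_dataset.records)
    return X, y, schema


@pytest.fixture()
def rng():
    return np.random.default_rng(2040)
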