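import numpy as np
import pytest

from duonorm import normalize, synthdata


@pytest.fixture(scope="session")
def small_config():
    return synthdata.SyntheticConfig(
        n_probesets=300, probes_per_set=6, n_per_group=(6, 6),
        de_fraction=0.05, effect_log2=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthdata.gen_probe_data(small_config)


@pytest.fixture(scope="session")
def small_mas(small_dataset):
    return normalize.mas5_like(small_dataset)


@pytest.fixture(scope="session")
def small_rma(small_dataset):
    return normalize.rma(small_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
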