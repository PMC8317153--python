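import pytest

from graphsig import GeneratorConfig, featurize_batch, generate_labels, generate_molecules


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_molecules=60, seed=7)


@pytest.fixture(scope="session")
def small_molecules(small_config):
    return generate_molecules(small_config)


@pytest.fixture(scope="session")
def small_labels(small_config, small_molecules):
    labels, gi50 = generate_labels(small_molecules, small_config)
    return labels, gi50


@pytest.fixture(scope="session")
def medium_config():
    return GeneratorConfig(n_molecules=200, seed=11)


@pytest.fixture(scope="session")
def medium_molecules(medium_config):
    return generate_molecules(medium_config)


@pytest.fixture(scope="session")
def medium_features(medium_molecules):
    matrix, failures = featurize_batch(medium_molecules)
    assert len(failures) == 0
    return matrix
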