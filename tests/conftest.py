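import numpy as np
import pytest

from lgtfate.synth import SimulationConfig, simulate_cohort, write_fixture_bundle


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact cohort used by most integration-level tests."""
    return SimulationConfig(seed=7, n_lgt_genes_per_accession=12, degeneration_log2fc=3.0)


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def bundle_dir(cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(cohort, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
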