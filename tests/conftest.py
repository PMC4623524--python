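import warnings

import numpy as np
import pytest

from skim2organelle import skimsim


@pytest.fixture(scope="session")
def mock_genome():
    """Default mock genome, fixed seed, shared across the suite."""
    return skimsim.build_mock_genome(skimsim.MockGenomeSpec(seed=7))


@pytest.fixture(scope="session")
def cp_reads(mock_genome):
    """Error-free 100x plastid reads from the default mock genome."""
    return skimsim.simulate_reads(mock_genome, {"cp": 100}, seed=42)


@pytest.fixture(scope="session")
def uniform_reads(mock_genome):
    """A uniform 4x whole-genome library (every component at the same
    per-base coverage), the study condition for copy-number estimation."""
    cov = {name: 4 for name in mock_genome.components}
    return skimsim.simulate_reads(mock_genome, cov, seed=11)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(987_654_321)
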