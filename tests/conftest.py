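import numpy as np
import pytest

from viroscreen.pipeline import run_orfan_pipeline
from viroscreen.synthetic import SyntheticConfig, generate_virome


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def virome(default_config):
    """Contigs + truth of the default seed-42 fixture (50 host, 6 known, 3 ORFan)."""
    return generate_virome(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """Full map -> screen run on the default seed-42 fixture."""
    return run_orfan_pipeline(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
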