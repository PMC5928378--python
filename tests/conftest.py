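import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def rdhc_protein():
    """One default-architecture RdhC-like protein with its truth row."""
    from rdhc_miner.synthetic_data import generate_rdhc_protein

    return generate_rdhc_protein(seed=3, protein_id="pcec_like", genome_id="g01")
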