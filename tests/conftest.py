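import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from interalu.primer_model import ConsensusRegistry, primer_from_name
from interalu.synthetic_data import simulate_genome


@pytest.fixture(scope="session")
def registry():
    return ConsensusRegistry.bundled()


@pytest.fixture(scope="session")
def primers(registry):
    """The assay's H/T primer pair derived from the bundled consensus."""
    return [
        primer_from_name(registry, "AluY278T18"),
        primer_from_name(registry, "AluY66H21"),
    ]


@pytest.fixture(scope="session")
def clean_genome(registry):
    """Zero-divergence genome with planted full-length Alu copies (truth known)."""
    return simulate_genome(
        length=200_000, n_alus=60, divergence=0.0, registry=registry, seed=11
    )
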