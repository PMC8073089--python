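import pytest
from hypothesis import HealthCheck, settings

from mitotile import CircularGenome, synthetic_reference

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
from mitotile.align import CircularIndex
from mitotile.scenarios import demo_panel


@pytest.fixture(scope="session")
def genome():
    return synthetic_reference()


@pytest.fixture(scope="session")
def panel(genome):
    return demo_panel(genome)


@pytest.fixture(scope="session")
def index(genome):
    return CircularIndex(genome)


@pytest.fixture
def toy_genome():
    return CircularGenome(name="toy", sequence="ACGTT")
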