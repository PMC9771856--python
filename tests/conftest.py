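import numpy as np
import pytest

from polyrep import (
    InitiationScenario,
    SpeedMode,
    build_paper_int,
    simulate,
)


@pytest.fixture(scope="session")
def paper_model():
    """Default 13-segment fragment, 100-kbp flanks, dna speed mode."""
    return build_paper_int(100.0, SpeedMode.DNA)


@pytest.fixture(scope="session")
def paper_model_stated():
    return build_paper_int(100.0, SpeedMode.STATED)


@pytest.fixture(scope="session")
def sync_records(paper_model):
    """One synchronous N=1024 run shared across read-only tests."""
    return simulate(paper_model, InitiationScenario.synchronous(), 1024, 2.0, seed=7)


@pytest.fixture(scope="session")
def window60_records(paper_model):
    return simulate(
        paper_model, InitiationScenario.uniform_window(60.0), 1024, 2.0, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
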