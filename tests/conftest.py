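import numpy as np
import pytest
from hypothesis import settings

from rvvm import BetaPrior, paper_bird_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def birds():
    """The fixed 50-bird banding survey."""
    return paper_bird_fixture()


@pytest.fixture(scope="session")
def rho_samples(birds):
    """The three protocol samples, keyed rho1 / rho2 / rho3."""
    return {
        p: birds.protocol_sample(protocol=p, with_truth=False)
        for p in ("rho1", "rho2", "rho3")
    }


@pytest.fixture(scope="session")
def naive_prior():
    return BetaPrior(15.0, 15.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200924)
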