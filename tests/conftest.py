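import numpy as np
import pytest

from frugitrack.synthetic import generate_study


@pytest.fixture(scope="session")
def small_study():
    """A 4-bat study (2 commuters, 3 sessions): fast but structurally complete."""
    return generate_study(n_bats=4, commuter_fraction=0.5, sessions=3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
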