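import numpy as np
import pytest

from perturbsig import StudyConfig, closure, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study with the default planted effects."""
    config = StudyConfig(n_per_group=6, P=50, depth=5000, seed=11)
    return generate_study(config)


def random_composition(rng, n, p):
    """Strictly positive random composition via Dirichlet draws."""
    return closure(rng.dirichlet(np.ones(p), size=n) + 1e-12)
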