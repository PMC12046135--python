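import numpy as np
import pytest

from bagpa import synthgen


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort under the default generative conditions."""
    return synthgen.generate_cohort(synthgen.GenerativeConfig(n_participants=3000, seed=42))


@pytest.fixture(scope="session")
def linear_cohort():
    """Linear-only activity effect (no U-shape): the mediation/quartile testbed."""
    cfg = synthgen.GenerativeConfig(
        n_participants=3000,
        seed=43,
        u_shape={"pa_optimum": 8.2, "curvature": 0.0},
    )
    return synthgen.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, cheap cohort for plumbing tests."""
    cfg = synthgen.GenerativeConfig(
        n_participants=600,
        seed=7,
        n_informative_idps=8,
        n_redundant_clusters=2,
        cluster_size=2,
        n_noise_idps=40,
    )
    return synthgen.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
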