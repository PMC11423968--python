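import numpy as np
import pytest

from primacyhull.synth import WorldConfig, make_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_world():
    """A small planted world shared by unit tests (fast to generate)."""
    cfg = WorldConfig(
        n_receptors=15,
        dimension=3,
        p=4,
        n_odorants=30,
        n_kc=120,
        claws_per_kc=3,
        claw_noise_fraction=0.0,
        missing_rate=0.2,
        affinity_noise=0.02,
        hull_directions=2000,
        seed=42,
        preset="tiny",
    )
    return make_world(cfg)
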