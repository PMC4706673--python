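import numpy as np
import pytest

from collagenkit.forcespec import Cantilever


@pytest.fixture(scope="session")
def cantilever() -> Cantilever:
    """The spherically tipped probe used throughout: R = 1 um, k = 3 N/m."""
    return Cantilever(spring_constant=3.0, tip_radius=1.0)


@pytest.fixture(scope="session")
def tendon_map():
    """Aligned, D-banded synthetic height map at 9.76 nm pixel spacing."""
    from collagenkit.synthetic import gen_heightmap

    return gen_heightmap(preset="tendon", seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
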