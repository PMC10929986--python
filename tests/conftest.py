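import numpy as np
import pytest

from photonblock.fixtures import FixtureSpec, make_field

ARCHETYPES = ["round_mantle_lungs", "pelvis_ovaries", "thin_mantle_lungs"]


@pytest.fixture(params=ARCHETYPES)
def archetype(request) -> str:
    return request.param


@pytest.fixture
def field(archetype):
    return make_field(FixtureSpec(archetype=archetype, rng_seed=1))


@pytest.fixture
def round_field():
    return make_field(FixtureSpec(archetype="round_mantle_lungs", rng_seed=1))


def random_star_polygon(rng: np.random.Generator, n: int = 12,
                        r_lo: float = 5.0, r_hi: float = 40.0) -> np.ndarray:
    """A guaranteed-simple polygon: random radii at sorted random angles."""
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    # keep angular gaps healthy so no two vertices nearly coincide
    while np.any(np.diff(angles) < 0.05):
        angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    radii = rng.uniform(r_lo, r_hi, n)
    return np.c_[radii * np.cos(angles), radii * np.sin(angles)]
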