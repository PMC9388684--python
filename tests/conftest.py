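import numpy as np
import pytest

from endoseg.annotations import make_target
from endoseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def hex_phantom():
    """Noiseless hexagonal-lattice phantom (HEX truth = 100%)."""
    return generate_phantom(PhantomConfig(regularity=1.0, area_sigma=0.0, seed=1))


@pytest.fixture(scope="session")
def irregular_phantom():
    """Noiseless jittered phantom with lognormal cell areas."""
    return generate_phantom(PhantomConfig(regularity=0.5, area_sigma=0.25, seed=7))


@pytest.fixture(scope="session")
def hex_targets(hex_phantom):
    return {k: make_target(hex_phantom.annotation, k).pixels
            for k in ("edge", "body", "blob", "roi")}


@pytest.fixture(scope="session")
def small_phantom():
    """Small, quick phantom for pipeline mechanics tests."""
    return generate_phantom(PhantomConfig(shape=(160, 160), mean_cell_diameter=20,
                                          regularity=0.6, area_sigma=0.2, seed=3))
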