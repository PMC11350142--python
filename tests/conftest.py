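import numpy as np
import pytest

from worldseasons.synthetic import ArchetypeSpec, make_pixel


@pytest.fixture(scope="session")
def archetype_pixels():
    """Noise-free archetype pixels (northern hemisphere) keyed by name."""
    return {
        arch: make_pixel(ArchetypeSpec(archetype=arch))
        for arch in (
            "temperate", "tropical_unimodal", "tropical_bimodal",
            "desert_hot", "desert_cold", "arctic",
        )
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240827)
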