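import numpy as np
import pytest

from cypmd.synthetic import MembraneSystemSpec, make_membrane_system


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def clean_membrane():
    """Noise-free membrane system with tilt 60 deg, depth 37 A."""
    return make_membrane_system(
        MembraneSystemSpec(tilt_deg=60.0, bury_depth=37.0, noise_sd=0.0, seed=7)
    )
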