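import numpy as np
import pytest

from cartfilm import ContactMask, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_mask():
    return ContactMask(center_x=32.0, center_y=32.0, radius=28.0)


@pytest.fixture
def small_spec():
    """Desk-fast sliding scenario: 12 cycles at 2 s, 96x96 px, 6 clusters."""
    return SyntheticSpec(
        shape=(96, 96),
        mask=ContactMask(center_x=48.0, center_y=48.0, radius=42.0),
        n0=6,
        duration=24.0,
        n_cycles=12,
        f_end=0.75,
        seed=7,
    )
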