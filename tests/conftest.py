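import numpy as np
import pytest

import deerpol as dp


@pytest.fixture
def t_grid():
    """Standard 80-point signed time axis, µs."""
    return np.linspace(-1.0, 4.0, 80)


@pytest.fixture
def background_truth():
    """Monoradical truth in the high-field/low-T regime (ε = 0.70)."""
    return dp.BackgroundFitModel(V0=1.0, k=1.0, t0=0.0, qB=3.6, epsilon=0.70)


@pytest.fixture
def biradical_truth():
    """Biradical truth: 3.7 nm Gaussian pair over a 0.5 µs⁻¹ background."""
    return dp.BiradicalFitModel(
        V0=1.0, k=0.5, t0=0.0, qB=4.2, epsilon=0.70,
        r0=3.7, w=0.2, qF=1.0, mod_depth=0.4,
    )
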