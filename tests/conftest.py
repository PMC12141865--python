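import numpy as np
import pytest

from phagepst.io_tables import GrowthCurve

GRID = np.arange(0.0, 24.0 + 1e-9, 0.25)


@pytest.fixture
def linear_control():
    """Control rising linearly 0.1 -> 1.1 OD over 24 h (AUC = 14.4)."""
    return GrowthCurve("ctrl", GRID, 0.1 + GRID / 24.0)


@pytest.fixture
def flat_with():
    """Infected well pinned at OD 0.1 (AUC over 24 h = 2.4)."""
    return GrowthCurve("with", GRID, np.full_like(GRID, 0.1))
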