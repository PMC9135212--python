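import numpy as np
import pytest

import pestmap as pm


@pytest.fixture
def grid33():
    """Single-component 3x3 rook lattice."""
    return pm.make_lattice(3, 3, 1, seed=7)


@pytest.fixture
def toy_panel():
    """2x2 lattice, two periods, small hand-checkable counts with offsets."""
    lattice = pm.make_lattice(2, 2, 1, population_range=(1000.0, 1000.0), seed=3)
    panel = pm.PanelCounts(
        area_ids=list(lattice.area_ids),
        periods=[0, 1],
        y=np.array([[3.0, 1.0], [2.0, 4.0], [0.0, 2.0], [5.0, 1.0]]),
        population=np.full((4, 2), 1000.0),
        expected=np.array([[2.0, 2.5], [3.0, 1.5], [1.0, 2.0], [4.0, 2.0]]),
    )
    return lattice, panel


@pytest.fixture
def toy_state():
    """A generic finite state for the 2x2x2 toy panel."""
    rng = np.random.default_rng(11)
    return {
        "b0": 0.3,
        "u": np.array([0.1, -0.2, 0.05, 0.05]),
        "v": rng.normal(0, 0.1, 4),
        "gamma": np.array([0.2, -0.2]),
        "phi": np.array([-0.1, 0.1]),
        "delta": rng.normal(0, 0.1, (4, 2)),
        "tau_u": 3.0,
        "tau_v": 2.0,
        "tau_gamma": 5.0,
        "tau_phi": 4.0,
        "tau_delta": 6.0,
    }
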