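import numpy as np
import pytest

import membranemc as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_cube():
    return m.generate_box((0, 0, 0), (1, 1, 1))


@pytest.fixture
def small_grid():
    """3x3 flat grid, 1 µm side: 9 vertices, 8 faces, one interior vertex."""
    return m.generate_flat_grid(3, 3, 1.0)


@pytest.fixture
def icosphere2():
    return m.generate_icosphere(2, 1.0, 0.0, seed=42)


def make_grid_state(seed=0, nx=6, ny=6, side=1.0, sigma=0.02, kappa1=30.0):
    """Clamped flat-grid SimState used by several engine tests."""
    from membranemc import mc_engine as eng
    mesh = m.generate_flat_grid(nx, ny, side)
    cfg = eng.SimConfig(box_lo=(-1, -1, -5), box_hi=(side + 1, side + 1, 5),
                        sigma=sigma, elastic=m.ElasticParams(kappa1, 2e6))
    return eng.SimState(config=cfg, rng=np.random.default_rng(seed), mesh=mesh)
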