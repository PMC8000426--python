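import numpy as np
import pytest

import colorib as cl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def palette4():
    """4 chips in a 3-4-5-friendly layout; simple enough to hand-compute."""
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 3.0, 4.0],
        [10.0, 0.0, 0.0],
        [10.0, 3.0, 4.0],
    ])
    return cl.Palette(
        chip_ids=np.arange(1, 5), rows=list("AABB"), cols=np.arange(4),
        coords=coords, prior=np.full(4, 0.25),
    )


@pytest.fixture
def palette5():
    coords = np.array([
        [0.0, 0.0, 0.0],
        [8.0, 0.0, 0.0],
        [0.0, 8.0, 0.0],
        [20.0, 0.0, 0.0],
        [20.0, 20.0, 0.0],
    ])
    return cl.Palette(
        chip_ids=np.arange(1, 6), rows=list("AAAAA"), cols=np.arange(5),
        coords=coords, prior=np.full(5, 0.2),
    )


@pytest.fixture
def blob_palette():
    return cl.make_blob_palette(2, 4, separation=60.0, sd=2.0, seed=0)


@pytest.fixture(scope="session")
def standin():
    return cl.wcs_standin_palette()


@pytest.fixture(scope="session")
def meanings(standin):
    return cl.build_meanings(standin, 64.0)


@pytest.fixture(scope="session")
def standin_curve(standin, meanings):
    """Annealed theoretical-limit curve on the 330-chip synthetic palette.

    Shared across tests; moderate schedule density keeps it to ~1-2 min.
    """
    return cl.compute_ib_curve(meanings, standin, n_beta=80, tol=1e-9,
                               max_iter=1000, store_encoders=True,
                               envelope=False)
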