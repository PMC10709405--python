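import numpy as np
import pytest

from tomodl import (AcquisitionSpec, ForwardModel, Geometry, PhantomSpec,
                    build_sampling, make_phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def geom16():
    return Geometry.uniform(16, 24)


@pytest.fixture(scope="session")
def model16(geom16):
    return ForwardModel(geom16)


@pytest.fixture(scope="session")
def model16_sub(geom16):
    return ForwardModel(geom16, build_sampling(24, 3, 0))


@pytest.fixture(scope="session")
def shepp64():
    return make_phantom(PhantomSpec(size_px=64, kind="shepp_logan"))


@pytest.fixture(scope="session")
def ellipses64():
    return make_phantom(PhantomSpec(size_px=64, kind="random_ellipses", seed=7))


@pytest.fixture(scope="session")
def acq360():
    """Full-turn acquisition at 1-degree steps (scaled-down angle grid)."""
    return AcquisitionSpec(n_angles_full=360, angle_step_deg=1.0)


def dense_matrix(model):
    """Dense operator matrix built by projecting each unit basis image."""
    n = model.geometry.image_size_px
    cols = []
    for j in range(n * n):
        e = np.zeros(n * n)
        e[j] = 1.0
        cols.append(model.project(e.reshape(n, n)).ravel())
    return np.stack(cols, axis=1)
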