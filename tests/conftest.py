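import numpy as np
import pytest

from nucleofold.synth import get_geometry_preset, get_linker_preset, sample_scene


@pytest.fixture(scope="session")
def pn1_preset():
    return get_linker_preset("PN1")


@pytest.fixture(scope="session")
def pn56_preset():
    return get_linker_preset("PN56")


@pytest.fixture(scope="session")
def pn1_geometry():
    return get_geometry_preset("PN1")


@pytest.fixture(scope="session")
def small_scene():
    """A small PN1 scene reused by read-only tests."""
    return sample_scene("PN1", n_arrays=12, array_size_range=(8, 12), seed=101)


@pytest.fixture(scope="session")
def large_scene():
    """A larger PN1 scene (~550 nucleosomes) for statistics tests."""
    return sample_scene("PN1", n_arrays=50, array_size_range=(10, 12), seed=11)


def brute_force_nearest(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive all-pairs nearest-neighbour scan (test oracle)."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    idx = np.argmin(d, axis=1)
    return d[np.arange(n), idx], idx
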