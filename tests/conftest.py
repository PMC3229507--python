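import numpy as np
import pytest

from ionpore.trajectory import PoreGeometry, Trajectory


def make_trajectory(z_series, species="anion", box=(40.0, 40.0, 80.0), dt=1.0):
    """Trajectory with prescribed z coordinates.

    ``z_series`` is (n_frames, n_particles) or a 1D series for a single
    particle; x and y stay at the origin.
    """
    z = np.asarray(z_series, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n_frames, n_particles = z.shape
    pos = np.zeros((n_frames, n_particles, 3))
    pos[:, :, 2] = z
    sp = (
        np.asarray(species, dtype="U16")
        if not isinstance(species, str)
        else np.full(n_particles, species, dtype="U16")
    )
    return Trajectory(
        times=dt * np.arange(n_frames),
        ids=np.arange(n_particles),
        species=sp,
        positions=pos,
        box=np.asarray(box, dtype=float),
    )


@pytest.fixture
def pore():
    return PoreGeometry(-15.0, 15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
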