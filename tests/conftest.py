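"""Shared fixtures and independent oracles.

The Mueller-calculus oracle reproduces analyzer-channel intensities for
circular light through a linear retarder entirely from textbook Mueller
matrices — an algebra independent of the Jones-propagation path used by
the simulator.
"""

import numpy as np
import pytest

from holopol.scene import OpticalConfig


@pytest.fixture(scope="session")
def cfg():
    """Default optics with a short recording distance for small grids."""
    return OpticalConfig(propagation_distance=2e-3)


def mueller_retarder(delta: float, theta: float) -> np.ndarray:
    """Textbook Mueller matrix of a linear retarder (fast axis theta)."""
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c * c + s * s * cd, c * s * (1 - cd), -s * sd],
            [0, c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [0, s * sd, -c * sd, cd],
        ]
    )


def oracle_channels(delta: float, theta: float, transmittance: float = 1.0) -> dict:
    """Analyzer-channel intensities for the simulator's illumination.

    Input Stokes vector (1, 0, 0, -1) (the circular state matching the
    package's Jones convention); an ideal linear analyzer at angle
    ``alpha`` transmits (S0 + S1 cos 2a + S2 sin 2a) / 2.
    """
    s = transmittance**2 * (mueller_retarder(delta, theta) @ np.array([1.0, 0, 0, -1.0]))
    out = {}
    for adeg in (0, 45, 90, 135):
        a = np.deg2rad(adeg)
        out[adeg] = 0.5 * (s[0] + s[1] * np.cos(2 * a) + s[2] * np.sin(2 * a))
    return out


def random_blob_mask(rng, size: int = 40) -> np.ndarray:
    """A random small connected-ish pixel blob for geometry property tests."""
    from skimage.morphology import dilation, disk

    m = np.zeros((size, size), dtype=bool)
    n = int(rng.integers(1, 60))
    rr = rng.integers(5, size - 5, n)
    cc = rng.integers(5, size - 5, n)
    m[rr, cc] = True
    return dilation(m, disk(int(rng.integers(0, 3))))
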