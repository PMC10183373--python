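"""Shared fixtures: small volumes, digitized balls, blob generators."""

from __future__ import annotations

import numpy as np
import pytest

from actimesh import Volume, labels_from_mask


def digitized_ball(n: int, center, radius: float) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = np.asarray(center)
    return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius ** 2


def ball_dt(n: int, centers, radius: float) -> Volume:
    """Erosion-depth distance transform of a union of digitized balls."""
    mask = np.zeros((n, n, n), dtype=bool)
    for c in centers:
        mask |= digitized_ball(n, c, radius)
    triplet = labels_from_mask(Volume(mask.astype(np.uint8), (1, 1, 1)))
    return Volume(triplet.dt.data.astype(float), (1, 1, 1))


def random_blob(rng, n: int = 32, n_seeds: int = 3) -> np.ndarray:
    """Random connected-ish blob mask from a union of random balls."""
    mask = np.zeros((n, n, n), dtype=bool)
    for _ in range(n_seeds):
        c = rng.integers(6, n - 6, size=3)
        r = rng.integers(3, n // 4)
        mask |= digitized_ball(n, c, r)
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    def make(n=32, spacing=(1.0, 1.0, 1.0)):
        return Volume(np.zeros((n, n, n)), spacing)

    return make
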