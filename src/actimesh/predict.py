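"""Label predictors: the ground-truth oracle, a trainable miniature
network, and anisotropy resampling.

Any predictor maps a frame to the (mask, border, distance-transform)
label triplet the seeding stage consumes.  The *oracle* predictor
computes labels directly from ground-truth meshes (optionally corrupted
with seeded Gaussian noise on the distance transform) and is the
canonical way to exercise the downstream pipeline without training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .labels import DT_SATURATION, LabelTriplet, LossWeights, make_labels
from .mesh import TriMesh
from .unet import TinyUnet
from .volume import Volume

__all__ = [
    "PredictorSpec",
    "oracle_predict",
    "resample_isotropic",
    "train_tiny_unet",
]


@dataclass
class PredictorSpec:
    """Which predictor to use and how it is shaped.

    ``kind`` is ``"oracle"`` or ``"unet"``.  ``base_filters`` and
    ``depth`` only matter for the network kind; channel order is fixed
    (mask, border, dt) and the dt output is clipped to [0, 32].
    """

    kind: str = "oracle"
    patch_shape: tuple = (32, 32, 32)
    base_filters: int = 4
    depth: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("oracle", "unet"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")


def oracle_predict(gt_meshes: list[TriMesh], grid: Volume,
                   noise_sigma: float = 0.0, seed: int = 0) -> LabelTriplet:
    """Labels straight from ground-truth meshes.

    ``noise_sigma`` adds seeded Gaussian noise to the distance transform
    (clipped back to [0, 32]) to emulate an imperfect network prediction;
    the same seed reproduces the same corruption.
    """
    triplet = make_labels(gt_meshes, grid)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = triplet.dt.data.astype(float) + rng.normal(0.0, noise_sigma,
                                                           size=triplet.dt.shape)
        triplet = LabelTriplet(
            mask=triplet.mask,
            border=triplet.border,
            dt=grid.like(np.clip(noisy, 0.0, float(DT_SATURATION))),
        )
    return triplet


def resample_isotropic(vol: Volume) -> Volume:
    """Linearly interpolate along z until spacing matches the x-y plane.

    Volumes that are already isotropic are returned unchanged. The
    physical extent is preserved to within one voxel.
    """
    sz, sy, sx = vol.spacing
    if abs(sy - sx) > 1e-9:
        raise ValueError("in-plane spacing must be isotropic")
    if abs(sz - sx) < 1e-9:
        return vol
    factor = sz / sx
    out = zoom(vol.data.astype(float), (factor, 1.0, 1.0), order=1,
               mode="nearest", grid_mode=False)
    return Volume(out, (sx, sy, sx), vol.origin)


def train_tiny_unet(frames: list[tuple[Volume, LabelTriplet]],
                    spec: PredictorSpec | None = None, epochs: int = 10,
                    seed: int = 0, lr: float = 0.05,
                    weights: LossWeights | None = None) -> tuple[TinyUnet, list[float]]:
    """Train the miniature network on (image, labels) pairs.

    Deterministic for a fixed seed.  Returns the trained predictor and
    its per-epoch loss curve; raises :class:`TrainingError` on
    divergence.
    """
    spec = spec or PredictorSpec(kind="unet")
    net = TinyUnet(base_filters=spec.base_filters, seed=seed)
    curve = net.fit(frames, epochs=epochs, lr=lr, weights=weights)
    return net, curve
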