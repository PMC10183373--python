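"""Training labels from mesh sets, and the composite training loss.

A set of closed meshes is converted to three voxel labels: a binary
*mask* (union of mesh interiors), a binary *border* (mask voxels with a
face-adjacent outside neighbour), and an integer *distance transform*
whose value at a voxel is the 6-connected erosion depth at which it would
be removed (0 on the border, saturated at 32).  The distance transform is
"modified" in that it is nonzero only strictly inside the objects, which
is what makes it usable for seeding instance meshes.

The training loss is a weighted sum of Sørensen-Dice terms for border and
mask plus a log mean-square error for the distance transform.  The Dice
terms are implemented in the printed plugin form
``(|T∩P| + 1) / (|T| + |P| + 1)`` (soft intersection and sizes); the
conventional ``1 - 2|T∩P| / (|T| + |P|)`` is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mesh import TriMesh, binarize
from .volume import Volume

__all__ = [
    "DT_SATURATION",
    "LabelTriplet",
    "LossWeights",
    "make_labels",
    "labels_from_mask",
    "dice_loss",
    "log_mse_loss",
    "total_loss",
]

DT_SATURATION = 32

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connected


@dataclass
class LabelTriplet:
    """(mask, border, distance-transform) label volumes on one grid."""

    mask: Volume
    border: Volume
    dt: Volume

    def validate(self) -> None:
        m = self.mask.data.astype(bool)
        b = self.border.data.astype(bool)
        d = np.asarray(self.dt.data)
        if b[~m].any():
            raise ValueError("border voxels outside the mask")
        if (d[~m] != 0).any():
            raise ValueError("distance transform nonzero outside the mask")
        if (d[b] != 0).any():
            raise ValueError("distance transform nonzero on the border")
        if d.max(initial=0) > DT_SATURATION:
            raise ValueError(f"distance transform exceeds {DT_SATURATION}")
        interior = m & ~b
        if interior.any() and (d[interior] <= 0).any():
            raise ValueError("interior voxel with nonpositive distance transform")


@dataclass
class LossWeights:
    """Weights (w_e, w_k, w_d) for border, mask and distance-transform terms."""

    w_e: float = 1.0
    w_k: float = 1.0
    w_d: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_e, self.w_k, self.w_d) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_e == self.w_k == self.w_d == 0:
            raise ValueError("at least one loss weight must be positive")


def labels_from_mask(mask: Volume) -> LabelTriplet:
    """Label triplet from an existing binary mask volume.

    The erosion depth is computed as the 6-connected (taxicab) chamfer
    distance to the outside, minus one, which is identical to iterating
    binary erosion and recording removal depth but runs in linear time.
    The array boundary counts as outside.
    """
    m = mask.data.astype(bool)
    padded = np.pad(m, 1)
    cdt = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    depth = np.clip(cdt - 1, 0, DT_SATURATION).astype(np.uint8)
    border = m & (cdt == 1)
    return LabelTriplet(
        mask=mask.like(m.astype(np.uint8)),
        border=mask.like(border.astype(np.uint8)),
        dt=mask.like(depth),
    )


def make_labels(meshes: list[TriMesh], grid: Volume) -> LabelTriplet:
    """Mask / border / saturated distance transform from a mesh set.

    Meshes are voxelized jointly (union); separating touching instances is
    the seeding stage's job, via ridges of the distance transform.
    """
    mask = np.zeros(grid.shape, dtype=np.uint8)
    for mesh in meshes:
        mask |= binarize(mesh, grid).data.astype(np.uint8)
    return labels_from_mask(grid.like(mask))


def _check_shapes(T, P) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(T.data if isinstance(T, Volume) else T, dtype=float)
    p = np.asarray(P.data if isinstance(P, Volume) else P, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return t, p


def dice_loss(T, P, conventional: bool = False) -> float:
    """Sørensen-Dice loss between truth ``T`` and prediction ``P``.

    Default is the printed plugin form ``(|T∩P| + 1) / (|T| + |P| + 1)``
    with soft intersection ``Σ T·P``; ``conventional=True`` gives
    ``1 - 2 |T∩P| / (|T| + |P|)`` instead.
    """
    t, p = _check_shapes(T, P)
    inter = float((t * p).sum())
    size = float(t.sum() + p.sum())
    if conventional:
        return 1.0 - 2.0 * inter / size if size > 0 else 0.0
    return (inter + 1.0) / (size + 1.0)


def log_mse_loss(T, P, eps: float = 1e-8) -> float:
    """``log(mean((T - P)^2) + eps)``; the mean sits inside the log."""
    t, p = _check_shapes(T, P)
    return float(np.log(np.mean((t - p) ** 2) + eps))


def total_loss(pred: LabelTriplet, truth: LabelTriplet,
               weights: LossWeights | None = None, conventional: bool = False) -> float:
    """Composite loss ``w_e L_e(border) + w_k L_k(mask) + w_d L_d(dt)``."""
    w = weights or LossWeights()
    out = 0.0
    if w.w_e:
        out += w.w_e * dice_loss(truth.border, pred.border, conventional)
    if w.w_k:
        out += w.w_k * dice_loss(truth.mask, pred.mask, conventional)
    if w.w_d:
        out += w.w_d * log_mse_loss(truth.dt, pred.dt)
    return out
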