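"""Voxel volumes with anisotropic physical spacing.

All arrays are indexed ``(z, y, x)`` (TIFF page order) and all physical
coordinates are ``(z, y, x)`` tuples in micrometres.  The centre of voxel
``(k, j, i)`` sits at ``origin + (k*sz, j*sy, i*sx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D scalar voxel grid with physical spacing.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``. May hold raw intensities, a distance
        transform, or integer instance labels.
    spacing:
        Voxel side lengths ``(sz, sy, sx)`` in µm; all positive.
    origin:
        Physical position (µm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def float_data(self) -> np.ndarray:
        """float64 view/copy of ``data``, cached for repeated sampling."""
        fd = getattr(self, "_float_data", None)
        if fd is None:
            fd = self.data if self.data.dtype == np.float64 else self.data.astype(np.float64)
            object.__setattr__(self, "_float_data", fd)
        return fd

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Physical coordinates (µm) of voxel indices (may be fractional)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of physical points."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid holding ``data``."""
        if data.shape != self.data.shape:
            raise ValueError("data shape does not match grid")
        return Volume(data, self.spacing, self.origin)

    def empty_like(self, dtype=np.uint8) -> "Volume":
        return Volume(np.zeros(self.shape, dtype=dtype), self.spacing, self.origin)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)
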