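"""Image energies and nodal forces coupling meshes to voxel data.

Two image couplings drive mesh nodes along their outward normals:

* the *perpendicular gradient energy* — the negated squared directional
  derivative of intensity along the node normal, estimated with a
  Gaussian-derivative stencil.  Its finite-difference force attracts nodes
  to intensity edges (the rim of a bright, filled nucleus);
* the *perpendicular intensity energy* — the negated Gaussian-weighted
  mean intensity along the normal.  Its force climbs the intensity profile
  toward bright sheets (membranes); with a negative image weight it
  descends instead, which is how meshes settle onto the low rim of a
  distance transform.

Intrinsic forces (uniform Laplacian and its square) penalise surface area
and bending so meshes stay smooth and tend to shrink onto their target.
Intensity profiles are sampled at unit-pixel steps along the normal, where
one "pixel" is the smallest spacing component, with trilinear
interpolation clamped at the volume border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .mesh import TriMesh
from .volume import Volume

__all__ = [
    "KernelSpec",
    "DeformParams",
    "gaussian_derivative_kernel",
    "sample_intensity",
    "perpendicular_gradient_energy",
    "gradient_energy_force",
    "perpendicular_intensity_energy",
    "intensity_force",
    "intrinsic_forces",
]


@dataclass(frozen=True)
class KernelSpec:
    """Antisymmetric Gaussian-derivative stencil sampled at integer offsets.

    ``coefficients[i + half_width]`` holds the weight at offset ``i`` for
    ``i`` in ``[-half_width, half_width]``; the centre weight is zero and
    the stencil is odd (``k[-i] = -k[i]``).
    """

    sigma: float = 2.0
    half_width: int = 5
    coefficients: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.coefficients is None:
            i = np.arange(-self.half_width, self.half_width + 1, dtype=float)
            k = -i / (np.sqrt(2 * np.pi) * self.sigma ** 3) * np.exp(-(i ** 2) / (2 * self.sigma ** 2))
            object.__setattr__(self, "coefficients", k)
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if abs(self.coefficients[self.half_width]) > 1e-15:
            raise ValueError("centre coefficient must be zero")
        if np.abs(self.coefficients).sum() <= 0:
            raise ValueError("kernel must be non-trivial")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)

    @property
    def abs_sum(self) -> float:
        return float(np.abs(self.coefficients).sum())


def gaussian_derivative_kernel(sigma: float = 2.0, w: int = 5) -> KernelSpec:
    """Stencil ``k_i = -i / (sqrt(2 pi) sigma^3) exp(-i^2 / (2 sigma^2))``.

    The overall positive prefactor is immaterial: every energy/force below
    normalises by ``sum |k_i|``, so only the shape of the stencil matters.
    """
    return KernelSpec(sigma=sigma, half_width=w)


@dataclass
class DeformParams:
    """Parameters controlling mesh evolution.

    Attributes
    ----------
    alpha:
        Surface-area / stretch penalty weight (µm of restoring displacement
        per unit Laplacian). Positive values shrink and smooth.
    beta:
        Bending penalty weight on the squared Laplacian.
    w_img:
        Signed image-force weight. Positive attracts toward bright
        structure; negative (used on distance transforms) repels from it.
    kernel:
        Gaussian-derivative stencil for the image terms.
    max_iters, step_size, tol:
        Explicit-Euler iteration count cap, dimensionless step, and the
        displacement (µm/iteration) below which, sustained over
        ``convergence_window`` iterations, the mesh counts as steady.
    remesh_every, l_min_px, l_max_px:
        Remeshing cadence (iterations) and edge-length bounds in pixels
        (multiples of the smallest spacing). ``remesh_every=0`` disables.
    max_step_px:
        Per-vertex displacement cap per iteration, in pixels.
    """

    alpha: float = 0.05
    beta: float = 0.01
    w_img: float = 60.0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    max_iters: int = 1000
    step_size: float = 0.1
    tol: float = 0.01
    convergence_window: int = 10
    remesh_every: int = 50
    l_min_px: float = 1.0
    l_max_px: float = 3.0
    max_step_px: float = 0.5

    def __post_init__(self) -> None:
        if self.max_iters <= 0:
            raise ValueError("max_iters must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


# ---------------------------------------------------------------------------
# sampling


def sample_intensity(vol: Volume, x: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at physical points; clamped at the border.

    ``x`` may be a single ``(3,)`` point or an ``(..., 3)`` array.
    """
    pts = np.asarray(x, dtype=float)
    single = pts.ndim == 1
    idx = vol.world_to_index(pts.reshape(-1, 3))
    vals = map_coordinates(vol.float_data, idx.T, order=1, mode="nearest")
    if single:
        return float(vals[0])
    return vals.reshape(pts.shape[:-1])


def _pixel(vol: Volume) -> float:
    return min(vol.spacing)


def _profile_sum(vol: Volume, x: np.ndarray, n: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Normalised stencil response ``sum_i k_i I(x - i*h*n) / sum|k_i|``.

    The stencil is applied in convolution orientation (offset ``-i`` pairs
    with ``k_i``), so the response estimates the *positive* directional
    derivative of the Gaussian-smoothed profile along ``n``: positive on a
    profile increasing along the normal.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    h = _pixel(vol)
    offs = -kernel.offsets.astype(float) * h
    pos = x[:, None, :] + offs[None, :, None] * n[:, None, :]
    vals = sample_intensity(vol, pos)
    return vals @ kernel.coefficients / kernel.abs_sum


def perpendicular_gradient_energy(I: Volume, x, n, kernel: KernelSpec | None = None):
    """Negated squared directional-derivative estimate along ``n`` (<= 0)."""
    kernel = kernel or KernelSpec()
    g = _profile_sum(I, x, n, kernel)
    e = -(g ** 2)
    return float(e[0]) if np.asarray(x).ndim == 1 else e


def gradient_energy_force(I: Volume, x, n, params: DeformParams):
    """Central finite difference of the gradient energy, along ``n``.

    ``F = -(w_img / 2) [E(x + h n) - E(x - h n)] n`` with ``h`` one pixel.
    """
    xx = np.atleast_2d(np.asarray(x, dtype=float))
    nn = np.atleast_2d(np.asarray(n, dtype=float))
    h = _pixel(I)
    e_plus = perpendicular_gradient_energy(I, xx + h * nn, nn, params.kernel)
    e_minus = perpendicular_gradient_energy(I, xx - h * nn, nn, params.kernel)
    mag = -(params.w_img / 2.0) * (np.asarray(e_plus) - np.asarray(e_minus))
    f = np.atleast_1d(mag)[:, None] * nn
    return f[0] if np.asarray(x).ndim == 1 else f


def perpendicular_intensity_energy(I: Volume, x, n, sigma: float = 2.0, w: int = 5):
    """Negated Gaussian-weighted mean intensity along ``n``.

    Minimal (most negative) where the normal line crosses bright sheets.
    """
    xx = np.atleast_2d(np.asarray(x, dtype=float))
    nn = np.atleast_2d(np.asarray(n, dtype=float))
    h = _pixel(I)
    u = np.arange(-w, w + 1, dtype=float)
    g = np.exp(-(u ** 2) / (2 * sigma ** 2))
    g = g / g.sum()
    pos = xx[:, None, :] + (u * h)[None, :, None] * nn[:, None, :]
    vals = sample_intensity(I, pos)
    e = -(vals @ g)
    return float(e[0]) if np.asarray(x).ndim == 1 else e


def intensity_force(I: Volume, x, n, params: DeformParams):
    """Gradient ascent/descent of the mean-intensity energy along ``n``.

    ``F = w_img [sum_i k_i I(x + i h n) / sum|k_i|] n``: positive ``w_img``
    climbs toward bright structure, negative descends (distance-transform
    minima).
    """
    xx = np.atleast_2d(np.asarray(x, dtype=float))
    nn = np.atleast_2d(np.asarray(n, dtype=float))
    mag = params.w_img * _profile_sum(I, xx, nn, params.kernel)
    f = mag[:, None] * nn
    return f[0] if np.asarray(x).ndim == 1 else f


# ---------------------------------------------------------------------------
# intrinsic forces


def _uniform_laplacian(mesh: TriMesh, values: np.ndarray) -> np.ndarray:
    """L(v) = value_v - mean over edge neighbours."""
    e = mesh.edges_unique()
    acc = np.zeros_like(values)
    cnt = np.zeros(len(values))
    np.add.at(acc, e[:, 0], values[e[:, 1]])
    np.add.at(acc, e[:, 1], values[e[:, 0]])
    np.add.at(cnt, e[:, 0], 1)
    np.add.at(cnt, e[:, 1], 1)
    return values - acc / cnt[:, None]


def intrinsic_forces(mesh: TriMesh, alpha: float, beta: float) -> np.ndarray:
    """Smoothing/shrinking force ``-alpha L(x) - beta L²(x)`` per vertex.

    ``L`` is the uniform graph Laplacian of vertex positions; on a convex
    mesh ``L(x)`` points outward, so positive ``alpha`` shrinks the surface
    while flattening local irregularities, and ``beta`` penalises bending.
    Translation-invariant by construction.
    """
    if alpha == 0.0 and beta == 0.0:
        return np.zeros_like(mesh.vertices)
    L = _uniform_laplacian(mesh, mesh.vertices)
    out = -alpha * L
    if beta != 0.0:
        out = out - beta * _uniform_laplacian(mesh, L)
    return out
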