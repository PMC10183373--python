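"""Synthetic two-channel phantoms of cell aggregates with ground truth.

A phantom emulates the imaging situation the pipeline targets: a compact
aggregate of a few dozen cells, nuclei as filled bright ellipsoids
(diameter of order 8 µm), membranes as bright shells partitioning the
aggregate into cells, optical blur and camera noise, whole-aggregate
drift over time and occasional cell divisions.

Cells are the Voronoi partition of a ball around sampled nucleus
centres; nuclei are randomly oriented ellipsoids (axis ratio <= 1.5, so
segmentation meshes must genuinely deform) kept strictly inside their
cells and mutually non-overlapping.  Ground-truth meshes come from the
noiseless geometry: nucleus meshes are analytic ellipsoid surfaces, cell
meshes are raycast over the Voronoi regions.

What it does not emulate: realistic light-sheet PSFs, photobleaching,
dye-accumulation artifacts, or irregular (non-star-convex) cell shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError
from .mesh import TriMesh, make_icosphere, raycast_from_region
from .volume import Volume

__all__ = ["PhantomSpec", "Frame", "generate_frame", "generate_timelapse"]


@dataclass
class PhantomSpec:
    """Geometry, optics and dynamics of a synthetic aggregate.

    Defaults give a half-resolution-regime aggregate: a 128³ grid of
    0.35 µm voxels holding ~10 cells with ~8 µm-diameter nuclei packed
    far enough apart that the non-overlap constraint rarely shrinks them.
    """

    n_cells: int = 10
    shape: tuple = (128, 128, 128)
    spacing: tuple = (0.35, 0.35, 0.35)
    aggregate_radius_um: float = 17.0
    nucleus_radius_um: float = 4.0
    nucleus_radius_sd_um: float = 0.3
    nucleus_axis_ratio_max: float = 1.3
    membrane_thickness_px: int = 2
    psf_sigma_px: float = 1.0
    gaussian_noise_sd: float = 0.02
    poisson_photons: float = 0.0  # 0 disables shot noise
    drift_um_per_frame: tuple = (0.0, 0.3, 0.3)
    jitter_sd_um: float = 0.05
    division_frames: tuple = ()
    mesh_subdivisions: int = 3
    seed: int = 0


@dataclass
class Frame:
    """One generated timepoint with full ground truth."""

    nuclear: Volume
    membrane: Volume
    nucleus_meshes: list
    cell_meshes: list
    nucleus_labels: Volume
    cell_labels: Volume
    frame_index: int = 0


@dataclass
class _Cell:
    instance_id: int
    center: np.ndarray  # µm
    radius: float  # nominal nucleus radius (geometric mean of semi-axes)
    axes: np.ndarray  # semi-axis scale factors, prod = 1
    rotation: np.ndarray  # 3x3


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _sample_centers(spec: PhantomSpec, rng, agg_center: np.ndarray) -> np.ndarray:
    d_min = 2.5 * spec.nucleus_radius_um
    r_max = spec.aggregate_radius_um - 1.1 * spec.nucleus_radius_um
    if r_max <= 0:
        raise GenerationError("aggregate too small for the requested nuclei")
    centers: list[np.ndarray] = []
    for _ in range(40000):
        if len(centers) == spec.n_cells:
            break
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = agg_center + u * r_max * rng.uniform() ** (1.0 / 3.0)
        if all(np.linalg.norm(p - c) >= d_min for c in centers):
            centers.append(p)
    if len(centers) < spec.n_cells:
        raise GenerationError(
            f"could not place {spec.n_cells} cells in an aggregate of radius "
            f"{spec.aggregate_radius_um} µm")
    return np.asarray(centers)


def _make_cells(spec: PhantomSpec, rng) -> tuple[list[_Cell], np.ndarray]:
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing)
    agg_center = shape * spacing / 2.0
    centers = _sample_centers(spec, rng, agg_center)
    cells = []
    for i, c in enumerate(centers):
        r = float(np.clip(rng.normal(spec.nucleus_radius_um, spec.nucleus_radius_sd_um),
                          0.5 * spec.nucleus_radius_um, 1.5 * spec.nucleus_radius_um))
        ratio = rng.uniform(1.0, spec.nucleus_axis_ratio_max)
        axes = np.array([ratio, 1.0, 1.0 / ratio])
        axes /= axes.prod() ** (1.0 / 3.0)
        cells.append(_Cell(instance_id=i + 1, center=c, radius=r,
                           axes=axes, rotation=_random_rotation(rng)))
    return cells, agg_center


def _constrain_nuclei(cells: list[_Cell], agg_center: np.ndarray,
                      agg_radius: float, margin: float = 0.4) -> None:
    """Shrink nuclei so each stays inside its Voronoi cell and the aggregate."""
    for cell in cells:
        d_wall = agg_radius - np.linalg.norm(cell.center - agg_center)
        d_neigh = min((np.linalg.norm(cell.center - o.center) for o in cells
                       if o is not cell), default=np.inf)
        cap = min(d_wall - margin, d_neigh / 2.0 - margin)
        longest = cell.radius * cell.axes.max()
        if longest > cap:
            cell.radius *= cap / longest


def _grid(spec: PhantomSpec) -> Volume:
    return Volume(np.zeros(spec.shape, dtype=np.float32), spec.spacing)


def _world_coords(spec: PhantomSpec) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def _nucleus_mask(cell: _Cell, spec: PhantomSpec) -> tuple[np.ndarray, tuple]:
    """Boolean ellipsoid mask over the cell's bounding sub-grid."""
    spacing = np.asarray(spec.spacing)
    semi = cell.radius * cell.axes
    reach = semi.max()
    lo = np.maximum(np.floor((cell.center - reach) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((cell.center + reach) / spacing).astype(int) + 2,
                    np.asarray(spec.shape))
    axes = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    rel = np.stack([zz, yy, xx], axis=-1) - cell.center
    local = rel @ cell.rotation  # into the ellipsoid frame
    q = (local / semi) ** 2
    mask = q.sum(axis=-1) <= 1.0
    return mask, tuple(slice(l, h) for l, h in zip(lo, hi))


def _nucleus_mesh(cell: _Cell, spec: PhantomSpec, frame_index: int) -> TriMesh:
    ico = make_icosphere(np.zeros(3), 1.0, spec.mesh_subdivisions,
                         frame_index=frame_index, instance_id=cell.instance_id)
    semi = cell.radius * cell.axes
    verts = (ico.vertices * semi) @ cell.rotation.T + cell.center
    mesh = TriMesh(verts, ico.faces, frame_index, cell.instance_id)
    if mesh.signed_volume() < 0:  # rotation may flip handedness
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def generate_frame(spec: PhantomSpec, cells: list[_Cell] | None = None,
                   agg_center: np.ndarray | None = None,
                   frame_index: int = 0, rng=None) -> Frame:
    """Generate one two-channel volume with ground-truth meshes and labels."""
    own_rng = np.random.default_rng(spec.seed) if rng is None else rng
    if cells is None:
        cells, agg_center = _make_cells(spec, np.random.default_rng(spec.seed))
        _constrain_nuclei(cells, agg_center, spec.aggregate_radius_um)
    grid = _grid(spec)
    coords = _world_coords(spec)

    # Voronoi partition of the aggregate ball
    in_ball = np.linalg.norm(coords - agg_center, axis=-1) <= spec.aggregate_radius_um
    d2 = np.stack([((coords - c.center) ** 2).sum(axis=-1) for c in cells])
    owner = np.argmin(d2, axis=0)
    cell_labels = np.zeros(spec.shape, dtype=np.uint16)
    for k, cell in enumerate(cells):
        cell_labels[in_ball & (owner == k)] = cell.instance_id

    nucleus_labels = np.zeros(spec.shape, dtype=np.uint16)
    for cell in cells:
        mask, sl = _nucleus_mask(cell, spec)
        nucleus_labels[sl][mask] = cell.instance_id

    nuclear = (nucleus_labels > 0).astype(np.float32)
    # membrane: cell-cell and cell-exterior boundary voxels, thickened
    interior = ndimage.grey_erosion(cell_labels, footprint=ndimage.generate_binary_structure(3, 1))
    exterior = ndimage.grey_dilation(cell_labels, footprint=ndimage.generate_binary_structure(3, 1))
    boundary = (cell_labels > 0) & ((interior != cell_labels) | (exterior != cell_labels))
    if spec.membrane_thickness_px > 1:
        boundary = ndimage.binary_dilation(
            boundary, ndimage.generate_binary_structure(3, 1),
            iterations=spec.membrane_thickness_px - 1)
        boundary &= cell_labels > 0
    membrane = boundary.astype(np.float32)

    if spec.psf_sigma_px > 0:
        nuclear = ndimage.gaussian_filter(nuclear, spec.psf_sigma_px)
        membrane = ndimage.gaussian_filter(membrane, spec.psf_sigma_px)
    if spec.poisson_photons > 0:
        nuclear = own_rng.poisson(np.maximum(nuclear, 0) * spec.poisson_photons
                                  ).astype(np.float32) / spec.poisson_photons
        membrane = own_rng.poisson(np.maximum(membrane, 0) * spec.poisson_photons
                                   ).astype(np.float32) / spec.poisson_photons
    if spec.gaussian_noise_sd > 0:
        nuclear = nuclear + own_rng.normal(0, spec.gaussian_noise_sd,
                                           size=spec.shape).astype(np.float32)
        membrane = membrane + own_rng.normal(0, spec.gaussian_noise_sd,
                                             size=spec.shape).astype(np.float32)

    nucleus_meshes = [_nucleus_mesh(c, spec, frame_index) for c in cells]
    cell_meshes = []
    for cell in cells:
        region = Volume(cell_labels == cell.instance_id, spec.spacing)
        cell_meshes.append(raycast_from_region(region, spec.mesh_subdivisions,
                                               frame_index=frame_index,
                                               instance_id=cell.instance_id))
    return Frame(
        nuclear=grid.like(np.asarray(nuclear, dtype=np.float32)),
        membrane=grid.like(np.asarray(membrane, dtype=np.float32)),
        nucleus_meshes=nucleus_meshes,
        cell_meshes=cell_meshes,
        nucleus_labels=grid.like(nucleus_labels),
        cell_labels=grid.like(cell_labels),
        frame_index=frame_index,
    )


def generate_timelapse(spec: PhantomSpec, n_frames: int) -> tuple[list[Frame], pd.DataFrame]:
    """Frames with whole-aggregate drift, jitter and scheduled divisions.

    Returns the frame list and a ground-truth track table with columns
    ``frame, instance_id, parent_id, z, y, x`` (centroids in µm).
    """
    if n_frames < 1:
        raise ValueError("need n_frames >= 1")
    rng = np.random.default_rng(spec.seed)
    cells, agg_center = _make_cells(spec, rng)
    _constrain_nuclei(cells, agg_center, spec.aggregate_radius_um)
    noise_rng = np.random.default_rng(spec.seed + 1)
    drift = np.asarray(spec.drift_um_per_frame, dtype=float)
    parents: dict[int, int | None] = {c.instance_id: None for c in cells}
    next_id = max(parents) + 1
    frames: list[Frame] = []
    rows = []
    for t in range(n_frames):
        if t > 0:
            jitter = rng.normal(0, spec.jitter_sd_um, size=(len(cells), 3))
            for c, j in zip(cells, jitter):
                c.center = c.center + drift + j
            agg_center = agg_center + drift
            if t in spec.division_frames:
                mother = max(cells, key=lambda c: c.radius)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                off = 0.6 * mother.radius * u
                daughter_r = mother.radius / 2 ** (1.0 / 3.0)
                d1 = _Cell(next_id, mother.center + off, daughter_r,
                           mother.axes.copy(), mother.rotation.copy())
                d2 = _Cell(next_id + 1, mother.center - off, daughter_r,
                           mother.axes.copy(), mother.rotation.copy())
                parents[next_id] = mother.instance_id
                parents[next_id + 1] = mother.instance_id
                next_id += 2
                cells = [c for c in cells if c is not mother] + [d1, d2]
            _constrain_nuclei(cells, agg_center, spec.aggregate_radius_um)
        frame = generate_frame(spec, cells=cells, agg_center=agg_center,
                               frame_index=t, rng=noise_rng)
        frames.append(frame)
        for c in cells:
            rows.append(dict(frame=t, instance_id=c.instance_id,
                             parent_id=parents[c.instance_id],
                             z=c.center[0], y=c.center[1], x=c.center[2]))
    return frames, pd.DataFrame(rows)
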