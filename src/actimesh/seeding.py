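"""From a distance-transform volume to initialized instance meshes.

Nuclei are seeded by thresholding the (predicted or synthetic) distance
transform — a threshold of 3 erosion depths separates cores of adjacent
nuclei that a threshold of 1 would merge — then growing the cores back
out with a marker-controlled watershed on the negated distance transform,
casting rays from each region's centre of mass to initialise a mesh, and
finally deforming each mesh with the perpendicular intensity energy of
the distance transform under a *negative* image weight.  The negative
weight pushes vertices down the distance transform, away from the object
interior, while a positive area penalty ``alpha`` shrinks the mesh so it
wraps the nucleus; seeds with no real object underneath never reach a
steady state, shrink, and are removed by the small-volume filter.

Membrane meshes reuse the nucleus meshes as initialisation and deform on
the membrane distance transform, again with a negative weight, with
steric repulsion keeping neighbouring cells from interpenetrating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .deformation import DEFAULT_V_MIN, DeformResult, deform, deform_cohort, filter_small
from .energies import DeformParams
from .errors import (DeformationError, DegenerateVertexError,
                     InvalidGeometryError, InvalidMeshError, RemeshError)
from .mesh import TriMesh, raycast_from_region
from .remesh import remesh
from .volume import Volume

__all__ = [
    "SeedRegion",
    "threshold_regions",
    "grow_regions",
    "seed_meshes",
    "segment_nuclei",
    "segment_membranes",
]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity for labeling

#: default minimum seed size: a 1 µm-radius ball, in µm³ (converted to voxels)
DEFAULT_S_MIN_UM3 = 4.0 / 3.0 * np.pi * 1.0 ** 3


@dataclass
class SeedRegion:
    """One connected seed component of the thresholded distance transform."""

    label: int
    voxels: np.ndarray  # (n, 3) int indices
    center_of_mass: np.ndarray  # physical µm
    size: int

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return m


def threshold_regions(dt: Volume, theta: float = 3.0,
                      s_min: int | None = None, s_max: int | None = None) -> list[SeedRegion]:
    """Connected components of ``{dt >= theta}``, filtered by voxel count.

    Components use 26-connectivity and are labeled in scan order, so the
    result is deterministic.  ``s_min`` defaults to the voxel count of a
    1 µm-radius ball; ``s_max`` is unbounded when omitted.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if s_min is None:
        s_min = max(1, int(round(DEFAULT_S_MIN_UM3 / dt.voxel_volume)))
    binary = np.asarray(dt.data) >= theta
    lab, n = ndimage.label(binary, structure=_CUBE)
    regions: list[SeedRegion] = []
    next_label = 1
    for comp in range(1, n + 1):
        vox = np.argwhere(lab == comp)
        size = len(vox)
        if size < s_min or (s_max is not None and size > s_max):
            continue
        com = dt.index_to_world(vox.mean(axis=0))
        regions.append(SeedRegion(label=next_label, voxels=vox,
                                  center_of_mass=com, size=size))
        next_label += 1
    return regions


def grow_regions(seeds: list[SeedRegion], dt: Volume, theta_floor: float = 1.0) -> list[SeedRegion]:
    """Expand seed cores over ``{dt >= theta_floor}`` by watershed on ``-dt``.

    Each output region contains its seed; regions stay disjoint because
    the watershed partitions the domain between markers.  Ties between
    markers resolve to the lower label.
    """
    if not seeds:
        return []
    shape = dt.shape
    markers = np.zeros(shape, dtype=np.int32)
    for s in seeds:
        m = s.mask(shape)
        if (markers[m] != 0).any():
            raise ValueError("seed regions overlap")
        markers[m] = s.label
    domain = np.asarray(dt.data) >= theta_floor
    if not domain.any():
        return seeds
    grown = watershed(-np.asarray(dt.data, dtype=float), markers=markers, mask=domain)
    out: list[SeedRegion] = []
    for s in seeds:
        vox = np.argwhere(grown == s.label)
        if len(vox) == 0:  # seed lay outside the domain; keep the core
            out.append(s)
            continue
        com = dt.index_to_world(vox.mean(axis=0))
        out.append(SeedRegion(label=s.label, voxels=vox, center_of_mass=com, size=len(vox)))
    return out


def seed_meshes(regions: list[SeedRegion], grid: Volume, subdivisions: int = 2,
                frame_index: int = 0) -> list[TriMesh]:
    """One raycast-initialised mesh per region; instance_id = region label.

    Regions on which raycasting fails (centre of mass outside the region)
    are skipped; skipped labels are recorded on the returned list's
    ``skipped`` attribute.
    """
    meshes: list[TriMesh] = []
    skipped: list[int] = []
    for region in regions:
        vol = Volume(region.mask(grid.shape), grid.spacing, grid.origin)
        try:
            mesh = raycast_from_region(vol, subdivisions=subdivisions,
                                       frame_index=frame_index, instance_id=region.label)
        except InvalidGeometryError:
            skipped.append(region.label)
            continue
        meshes.append(mesh)
    out = list(meshes)
    return _WithSkipped(out, skipped)


class _WithSkipped(list):
    """List of meshes carrying the labels of regions that failed raycasting."""

    def __new__(cls, items, skipped):
        return super().__new__(cls, items)

    def __init__(self, items, skipped):
        super().__init__(items)
        self.skipped = skipped


def segment_nuclei(dt: Volume, params: DeformParams | None = None, theta: float = 3.0,
                   s_min: int | None = None, s_max: int | None = None,
                   theta_floor: float = 1.0, v_min: float = DEFAULT_V_MIN,
                   subdivisions: int = 2, frame_index: int = 0) -> list[DeformResult]:
    """Full nucleus segmentation from a distance-transform volume.

    threshold -> watershed growth -> raycast seeding -> intensity-mode
    deformation with negative image weight -> small-volume filtering.
    Returns only the surviving results.
    """
    if np.asarray(dt.data).min(initial=0) < 0:
        raise ValueError("distance transform must be nonnegative")
    params = params or nucleus_dt_params(min(dt.spacing))
    if params.w_img >= 0:
        raise ValueError("nucleus deformation on a distance transform needs w_img < 0")
    seeds = threshold_regions(dt, theta=theta, s_min=s_min, s_max=s_max)
    grown = grow_regions(seeds, dt, theta_floor=theta_floor)
    meshes = seed_meshes(grown, dt, subdivisions=subdivisions, frame_index=frame_index)
    # normalise triangle size before evolving: the intrinsic force scales
    # with squared edge length, so un-remeshed seeds would feel a
    # shape-dependent shrink pressure
    h = min(dt.spacing)
    prepared = []
    for m in meshes:
        try:
            prepared.append(remesh(m, params.l_min_px * h, params.l_max_px * h))
        except (RemeshError, DegenerateVertexError):
            prepared.append(m)
    results = []
    for m in prepared:
        try:
            results.append(deform(m, dt, energy_mode="intensity", params=params))
        except (InvalidMeshError, DeformationError):
            continue  # degenerate seed (e.g. a 1-2 voxel blob): no mesh survives
    kept, _ = filter_small(results, v_min=v_min)
    return kept


def segment_membranes(nucleus_meshes: list[TriMesh], membrane_dt: Volume,
                      params: DeformParams | None = None,
                      v_min: float = DEFAULT_V_MIN) -> list[DeformResult]:
    """Membrane meshes grown outward from nucleus meshes.

    Each nucleus mesh is copied and deformed on the membrane distance
    transform with a negative image weight; the whole cohort evolves in
    lockstep with steric repulsion so neighbouring cells do not overlap.
    Instance ids are inherited from the nuclei.
    """
    if not nucleus_meshes:
        return []
    if np.asarray(membrane_dt.data).min(initial=0) < 0:
        raise ValueError("distance transform must be nonnegative")
    params = params or membrane_dt_params(min(membrane_dt.spacing))
    if params.w_img >= 0:
        raise ValueError("membrane deformation on a distance transform needs w_img < 0")
    h = min(membrane_dt.spacing)
    copies = []
    for m in nucleus_meshes:
        c = m.copy()
        try:
            c = remesh(c, params.l_min_px * h, params.l_max_px * h)
        except (RemeshError, DegenerateVertexError):
            pass
        copies.append(c)
    results = deform_cohort(copies, membrane_dt, energy_mode="intensity",
                            params=params, steric=True)
    kept, _ = filter_small(results, v_min=v_min)
    return kept


def nucleus_dt_params(pixel_um: float = 1.0) -> DeformParams:
    """Defaults for wrapping nuclei on a distance transform.

    The negative image weight descends the distance transform (outward);
    ``alpha`` shrinks the mesh so the two balance on the object rim.
    The balance is kept scale-free by expressing the area penalty per
    pixel (the distance-transform slope is one count per pixel while the
    Laplacian is physical): ``alpha`` scales as ``1/pixel`` and the step
    as ``pixel``, leaving the stability product unchanged.
    """
    return DeformParams(alpha=3.0 / pixel_um, beta=0.05 / pixel_um, w_img=-1.0,
                        max_iters=600, step_size=0.125 * pixel_um, tol=0.01)


def membrane_dt_params(pixel_um: float = 1.0) -> DeformParams:
    """Defaults for expanding nucleus meshes to the cell membrane.

    Membranes use a coarser triangulation than nuclei (edge bounds 1.5-4.5
    px instead of 1-3): cell surfaces are larger and smoother, and the
    coarser mesh keeps the cohort's steric bookkeeping cheap.
    """
    return DeformParams(alpha=2.5 / pixel_um, beta=0.05 / pixel_um, w_img=-1.0,
                        max_iters=600, step_size=0.15 * pixel_um, tol=0.01,
                        l_min_px=1.5, l_max_px=4.5)
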