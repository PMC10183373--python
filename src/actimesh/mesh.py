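"""Closed triangulated surfaces and their interaction with voxel grids.

A :class:`TriMesh` is the segmentation unit: one closed, outward-wound,
genus-0 triangle surface per nucleus or cell membrane, with vertices in
physical coordinates (µm, axis order ``(z, y, x)`` to match volumes).

This module provides mesh construction (icosphere templates, raycast
initialisation from sphere sets or voxel regions), geometry queries
(normals, bounding boxes, signed volume), and voxelization (point-in-
polyhedron scanline parity fill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy import ndimage

from .errors import DegenerateVertexError, InvalidGeometryError, InvalidMeshError
from .volume import Volume

__all__ = [
    "TriMesh",
    "SphereSet",
    "make_icosphere",
    "vertex_normals",
    "raycast_from_spheres",
    "raycast_from_region",
    "binarize",
    "points_inside",
    "bounding_box",
]


@dataclass
class TriMesh:
    """Closed triangulated surface in physical coordinates.

    Attributes
    ----------
    vertices:
        ``(V, 3)`` float array of points ``(z, y, x)`` in µm.
    faces:
        ``(F, 3)`` int array of vertex indices, wound so face normals point
        outward (signed volume > 0).
    frame_index:
        Time index of the frame the mesh belongs to.
    instance_id:
        Integer identity of the segmented object.
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame_index: int = 0
    instance_id: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidMeshError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidMeshError("faces must be (F, 3)")

    # -- combinatorics -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _edge_stats(self):
        """(unique edges, counts), cached against the faces array identity.

        Faces arrays are treated as immutable: every topology edit
        replaces the array, which invalidates the cache.
        """
        cache = getattr(self, "_edge_cache", None)
        if cache is not None and cache[0] is self.faces:
            return cache[1], cache[2]
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        self._edge_cache = (self.faces, uniq, counts)
        return uniq, counts

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges, each as a sorted index pair."""
        return self._edge_stats()[0]

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        return bool(np.all(self._edge_stats()[1] == 2))

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    # -- geometry ------------------------------------------------------

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                n = np.where(norm > 0, n / norm, 0.0)
        return n

    def signed_volume(self) -> float:
        """Enclosed volume (µm³) by the divergence theorem; > 0 if outward-wound."""
        v = self.vertices
        f = self.faces
        return float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())

    def centroid(self) -> np.ndarray:
        """Unweighted mean of vertex positions (µm)."""
        return self.vertices.mean(axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    # -- manipulation --------------------------------------------------

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.frame_index, self.instance_id)

    def translated(self, t) -> "TriMesh":
        out = self.copy()
        out.vertices = out.vertices + np.asarray(t, dtype=float)
        return out

    def validate(self) -> None:
        """Raise :class:`InvalidMeshError` unless closed, genus 0 and outward."""
        if not self.is_closed():
            raise InvalidMeshError("mesh is not closed (edge not shared by exactly 2 faces)")
        chi = self.euler_characteristic()
        if chi != 2:
            raise InvalidMeshError(f"Euler characteristic {chi} != 2 (genus-0 required)")
        if self.signed_volume() <= 0:
            raise InvalidMeshError("faces not consistently outward-wound (signed volume <= 0)")


@dataclass
class SphereSet:
    """Programmatic stand-in for manually positioned seed spheres.

    ``spheres`` is a list of ``(center, radius)`` with centers in µm
    ``(z, y, x)``.  The union must be connected so a single star-convex
    surface can wrap it.
    """

    spheres: list

    def __post_init__(self) -> None:
        if not self.spheres:
            raise ValueError("SphereSet needs at least one sphere")
        centers = np.asarray([c for c, _ in self.spheres], dtype=float)
        radii = np.asarray([r for _, r in self.spheres], dtype=float)
        if np.any(radii <= 0):
            raise ValueError("sphere radii must be positive")
        self.centers = centers
        self.radii = radii
        if len(centers) > 1 and not self._connected():
            raise ValueError("union of spheres is not connected")

    def _connected(self) -> bool:
        n = len(self.centers)
        d = np.linalg.norm(self.centers[:, None] - self.centers[None, :], axis=2)
        adj = d <= (self.radii[:, None] + self.radii[None, :])
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i])[0]:
                if j not in seen:
                    seen.add(int(j))
                    stack.append(int(j))
        return len(seen) == n


# ---------------------------------------------------------------------------
# construction


def make_icosphere(center, radius: float, subdivisions: int = 2,
                   frame_index: int = 0, instance_id: int = 0) -> TriMesh:
    """Subdivided icosahedron with all vertices at ``radius`` from ``center``.

    ``subdivisions`` s yields ``20 * 4**s`` faces.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float)
    # re-project exactly onto the unit sphere, then scale/translate
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    verts = verts * radius + np.asarray(center, dtype=float)
    return TriMesh(verts, np.asarray(ico.faces, dtype=np.int64),
                   frame_index=frame_index, instance_id=instance_id)


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Outward unit normal per vertex.

    The normal is the normalised average of the unit normals of incident
    faces; zero-area faces contribute nothing.  Raises
    :class:`DegenerateVertexError` if the average vanishes at some vertex.
    """
    fn = mesh.face_normals(normalize=True)
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], fn)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms < 1e-14):
        bad = int(np.argmin(norms))
        raise DegenerateVertexError(f"vertex {bad} has no defined normal")
    return acc / norms[:, None]


def raycast_from_spheres(spheres: SphereSet, subdivisions: int = 2,
                         frame_index: int = 0, instance_id: int = 0) -> TriMesh:
    """Star-convex mesh wrapping a union of spheres.

    An icosphere template is centred at the centroid of the sphere centres;
    each vertex is pushed along its ray to the farthest intersection with
    the union-of-spheres boundary.
    """
    c = spheres.centers.mean(axis=0)
    inside = np.linalg.norm(spheres.centers - c, axis=1) <= spheres.radii
    if not np.any(inside):
        raise InvalidGeometryError("centroid of sphere centers lies outside the union")
    template = make_icosphere(c, 1.0, subdivisions, frame_index, instance_id)
    dirs = template.vertices - c  # unit: icosphere radius 1

    # farthest positive root of |c + t d - cs|^2 = r^2 over all spheres
    t_best = np.full(len(dirs), -np.inf)
    for cs, r in zip(spheres.centers, spheres.radii):
        m = dirs @ (c - cs)
        q = float((c - cs) @ (c - cs)) - r * r
        disc = m * m - q
        ok = disc >= 0
        t = np.where(ok, -m + np.sqrt(np.maximum(disc, 0.0)), -np.inf)
        t_best = np.maximum(t_best, t)
    if np.any(~np.isfinite(t_best)) or np.any(t_best <= 0):
        raise InvalidGeometryError("a ray from the centroid misses the sphere union")
    out = template.copy()
    out.vertices = c + dirs * t_best[:, None]
    return out


def raycast_from_region(region: Volume, subdivisions: int = 2,
                        frame_index: int = 0, instance_id: int = 0) -> TriMesh:
    """Star-convex mesh wrapping a binary voxel region.

    Rays are cast from the region's centre of mass toward the vertices of
    an icosphere template; each vertex is repositioned to the centre of the
    farthest region voxel intersected by its ray.  The ray is marched at a
    quarter of the smallest voxel spacing for sub-voxel robustness.
    """
    data = region.data.astype(bool)
    if not data.any():
        raise ValueError("region is empty")
    com_idx = np.asarray(ndimage.center_of_mass(data), dtype=float)
    com_vox = tuple(np.round(com_idx).astype(int))
    if not data[com_vox]:
        raise InvalidGeometryError("region center of mass falls outside the region")
    com = region.index_to_world(com_idx)

    template = make_icosphere(com, 1.0, subdivisions, frame_index, instance_id)
    dirs = template.vertices - com  # unit vectors

    step = 0.25 * min(region.spacing)
    # farthest any region voxel can be from the com
    extent = np.linalg.norm(np.asarray(region.shape) * np.asarray(region.spacing))
    ts = np.arange(0.0, extent + step, step)
    pos = com[None, None, :] + ts[None, :, None] * dirs[:, None, :]  # (D, S, 3)
    idx = np.round(region.world_to_index(pos)).astype(int)  # nearest voxel
    valid = np.all((idx >= 0) & (idx < np.asarray(region.shape)), axis=2)
    hit = np.zeros(valid.shape, dtype=bool)
    iv = idx[valid]
    hit[valid] = data[iv[:, 0], iv[:, 1], iv[:, 2]]
    if not hit[:, 0].all():  # t=0 is the com voxel, inside by precondition
        raise InvalidGeometryError("ray origin not inside region")
    # last True along the march
    last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
    far_vox = idx[np.arange(len(dirs)), last]
    out = template.copy()
    out.vertices = region.index_to_world(far_vox)
    return out


# ---------------------------------------------------------------------------
# voxelization / containment


def _ray_crossings(vertices_idx: np.ndarray, faces: np.ndarray, nz: int, ny: int):
    """X-parity crossings of +x rays through integer (z, y) voxel centres.

    Vertices are in continuous index coordinates.  A tiny symbolic
    perturbation shifts the surface off the ray lattice so no ray passes
    exactly through a vertex or edge; the result is deterministic.
    """
    v = vertices_idx + np.array([2.611e-7, 1.377e-7, 0.0])
    p0 = v[faces[:, 0]]
    p1 = v[faces[:, 1]]
    p2 = v[faces[:, 2]]
    d1 = p1[:, :2] - p0[:, :2]  # (z, y) projections
    d2 = p2[:, :2] - p0[:, :2]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    zmin = np.maximum(np.ceil(np.minimum.reduce([p0[:, 0], p1[:, 0], p2[:, 0]])), 0).astype(int)
    zmax = np.minimum(np.floor(np.maximum.reduce([p0[:, 0], p1[:, 0], p2[:, 0]])), nz - 1).astype(int)
    ymin = np.maximum(np.ceil(np.minimum.reduce([p0[:, 1], p1[:, 1], p2[:, 1]])), 0).astype(int)
    ymax = np.minimum(np.floor(np.maximum.reduce([p0[:, 1], p1[:, 1], p2[:, 1]])), ny - 1).astype(int)
    cz = zmax - zmin + 1
    cy = ymax - ymin + 1
    keep = (np.abs(det) > 1e-14) & (cz > 0) & (cy > 0)
    if not keep.any():
        return np.empty(0, dtype=int), np.empty(0)
    p0, p1, p2 = p0[keep], p1[keep], p2[keep]
    d1, d2, det = d1[keep], d2[keep], det[keep]
    zmin, ymin, cz, cy = zmin[keep], ymin[keep], cz[keep], cy[keep]
    # ragged flattening: one row per (face, candidate z, candidate y)
    counts = cz * cy
    fidx = np.repeat(np.arange(len(counts)), counts)
    offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    zz = zmin[fidx] + offs // cy[fidx]
    yy = ymin[fidx] + offs % cy[fidx]
    rz = zz - p0[fidx, 0]
    ry = yy - p0[fidx, 1]
    l1 = (rz * d2[fidx, 1] - ry * d2[fidx, 0]) / det[fidx]
    l2 = (ry * d1[fidx, 0] - rz * d1[fidx, 1]) / det[fidx]
    inside = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
    if not inside.any():
        return np.empty(0, dtype=int), np.empty(0)
    fi = fidx[inside]
    l1i, l2i = l1[inside], l2[inside]
    x = (1.0 - l1i - l2i) * p0[fi, 2] + l1i * p1[fi, 2] + l2i * p2[fi, 2]
    return zz[inside] * ny + yy[inside], x


def binarize(mesh: TriMesh, grid: Volume) -> Volume:
    """Voxelize a closed mesh: 1 where the voxel centre lies inside.

    Point-in-polyhedron is decided by x-ray crossing parity with a symbolic
    perturbation of the surface, so the result is deterministic and exact
    for voxel centres off the surface.
    """
    if not mesh.is_closed():
        raise InvalidMeshError("binarize requires a closed mesh")
    nz, ny, nx = grid.shape
    vidx = grid.world_to_index(mesh.vertices)
    rid, xs = _ray_crossings(vidx, mesh.faces, nz, ny)
    out = np.zeros(grid.shape, dtype=np.uint8)
    if len(rid) == 0:
        return grid.like(out)
    order = np.lexsort((xs, rid))
    rid, xs = rid[order], xs[order]
    # crossings along each ray pair up (enter, exit); drop rays where a
    # grazing contact left an odd count
    is_start = np.r_[True, rid[1:] != rid[:-1]]
    run_id = np.cumsum(is_start) - 1
    counts = np.bincount(run_id)
    valid = (counts % 2 == 0)[run_id]
    rid, xs, run_id = rid[valid], xs[valid], run_id[valid]
    if len(rid) == 0:
        return grid.like(out)
    idx = np.arange(len(rid))
    is_start = np.r_[True, rid[1:] != rid[:-1]]
    run_start = np.maximum.accumulate(np.where(is_start, idx, 0))
    rank = idx - run_start
    a = np.ceil(xs[rank % 2 == 0]).astype(int)
    b = np.floor(xs[rank % 2 == 1]).astype(int)
    ray = rid[rank % 2 == 0]
    a = np.maximum(a, 0)
    b = np.minimum(b, nx - 1)
    keep = a <= b
    a, b, ray = a[keep], b[keep], ray[keep]
    if len(a):
        lens = b - a + 1
        base = np.repeat(ray * nx + a, lens)
        offs = np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
        out.ravel()[base + offs] = 1
    return grid.like(out)


def points_inside(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """Boolean containment test for arbitrary physical points.

    Same x-ray parity rule as :func:`binarize`, fully vectorized over
    query points and faces, with a bounding-box prefilter.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inside = np.zeros(len(pts), dtype=bool)
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    cand = np.all((pts >= lo) & (pts <= hi), axis=1)
    if cand.any():
        q = pts[cand]
        v = mesh.vertices + np.array([2.611e-7, 1.377e-7, 0.0])
        f = mesh.faces
        p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        d1 = p1[:, :2] - p0[:, :2]  # (z, y) plane
        d2 = p2[:, :2] - p0[:, :2]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        ok = np.abs(det) > 1e-14
        p0, p1, p2 = p0[ok], p1[ok], p2[ok]
        d1, d2, det = d1[ok], d2[ok], det[ok]
        rz = q[:, None, 0] - p0[None, :, 0]  # (Q, F)
        ry = q[:, None, 1] - p0[None, :, 1]
        l1 = (rz * d2[None, :, 1] - ry * d2[None, :, 0]) / det[None, :]
        l2 = (ry * d1[None, :, 0] - rz * d1[None, :, 1]) / det[None, :]
        hit = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
        x = ((1.0 - l1 - l2) * p0[None, :, 2] + l1 * p1[None, :, 2]
             + l2 * p2[None, :, 2])
        crossings = (hit & (x > q[:, None, 2])).sum(axis=1)
        inside[cand] = (crossings % 2).astype(bool)
    return inside if np.asarray(points).ndim == 2 else inside[0]


def bounding_box(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box ``(min_corner, max_corner)`` in µm."""
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh has no bounding box")
    return mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
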