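"""Isotropic-ish remeshing of closed triangle surfaces.

Keeps every edge length inside ``[l_min, l_max]`` by iterative
longest-edge bisection, shortest-edge collapse and tangential Laplacian
relaxation, while preserving closed-manifold topology and enclosed volume
(rescaled about the centroid when drift exceeds a small tolerance).

Deformation calls this periodically so that meshes stay well-conditioned
as they stretch over nuclei and membranes.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidMeshError, RemeshError
from .mesh import TriMesh, vertex_normals

__all__ = ["remesh"]

_EPS = 0.3  # fractional slack on the edge-length bounds
_MAX_PASSES = 12


def _edge_map(faces: np.ndarray) -> dict:
    """Map sorted edge tuple -> list of face indices."""
    em: dict = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            em.setdefault(key, []).append(fi)
    return em


def _split_long_edges(verts: list, faces: list, l_max: float) -> bool:
    """Bisect every edge longer than l_max once. Returns True if changed."""
    em = _edge_map(np.asarray(faces))
    va = np.asarray(verts)
    long_edges = []
    for (a, b), fids in em.items():
        if len(fids) != 2:
            raise RemeshError("non-manifold edge encountered during split")
        l = np.linalg.norm(va[a] - va[b])
        if l > l_max:
            long_edges.append((l, a, b, tuple(fids)))
    if not long_edges:
        return False
    long_edges.sort(reverse=True)
    dead_faces: set = set()
    for _, a, b, fids in long_edges:
        if dead_faces.intersection(fids):
            continue  # an adjacent face was already split this pass
        mid = 0.5 * (np.asarray(verts[a]) + np.asarray(verts[b]))
        m = len(verts)
        verts.append(mid)
        for fi in fids:
            f = faces[fi]
            # rotate so edge (a, b) is (f[0], f[1]) preserving winding
            for _ in range(3):
                if {f[0], f[1]} == {a, b}:
                    break
                f = (f[1], f[2], f[0])
            faces.append((f[0], m, f[2]))
            faces.append((m, f[1], f[2]))
            dead_faces.add(fi)
    for fi in sorted(dead_faces, reverse=True):
        faces.pop(fi)
    return True


def _collapse_short_edges(verts: list, faces: list, l_min: float) -> bool:
    """Collapse edges shorter than l_min to their midpoint (link condition)."""
    va = np.asarray(verts)
    em = _edge_map(np.asarray(faces))
    neigh: dict = {}
    for (a, b) in em:
        neigh.setdefault(a, set()).add(b)
        neigh.setdefault(b, set()).add(a)
    short = []
    for (a, b), fids in em.items():
        l = np.linalg.norm(va[a] - va[b])
        if l < l_min:
            short.append((l, a, b, tuple(fids)))
    if not short:
        return False
    short.sort()
    touched: set = set()
    remap = np.arange(len(verts))
    changed = False
    for _, a, b, fids in short:
        if a in touched or b in touched:
            continue
        opposite = set()
        for fi in fids:
            opposite.update(faces[fi])
        opposite -= {a, b}
        # link condition: shared neighbours must be exactly the two apices
        if neigh[a] & neigh[b] != opposite or len(opposite) != 2:
            continue
        mid = 0.5 * (np.asarray(verts[a]) + np.asarray(verts[b]))
        verts[a] = mid
        remap[b] = a
        touched.update(neigh[a] | neigh[b] | {a, b})
        changed = True
    if not changed:
        return False
    new_faces = []
    for f in faces:
        g = (int(remap[f[0]]), int(remap[f[1]]), int(remap[f[2]]))
        if len({g[0], g[1], g[2]}) == 3:
            new_faces.append(g)
    faces[:] = new_faces
    # drop orphaned vertices, compacting indices
    used = np.zeros(len(verts), dtype=bool)
    for f in faces:
        used[list(f)] = True
    new_index = np.cumsum(used) - 1
    verts[:] = [v for v, u in zip(verts, used) if u]
    faces[:] = [(int(new_index[f[0]]), int(new_index[f[1]]), int(new_index[f[2]])) for f in faces]
    return True


def _tangential_smooth(mesh: TriMesh, strength: float = 0.5, rounds: int = 2) -> None:
    for _ in range(rounds):
        normals = vertex_normals(mesh)
        acc = np.zeros_like(mesh.vertices)
        cnt = np.zeros(len(mesh.vertices))
        e = mesh.edges_unique()
        np.add.at(acc, e[:, 0], mesh.vertices[e[:, 1]])
        np.add.at(acc, e[:, 1], mesh.vertices[e[:, 0]])
        np.add.at(cnt, e[:, 0], 1)
        np.add.at(cnt, e[:, 1], 1)
        delta = acc / cnt[:, None] - mesh.vertices
        delta -= np.einsum("ij,ij->i", delta, normals)[:, None] * normals
        mesh.vertices = mesh.vertices + strength * delta


def remesh(mesh: TriMesh, l_min: float, l_max: float) -> TriMesh:
    """Return a mesh whose edges all lie in ``[l_min, l_max]`` (with slack).

    An already-conforming mesh is returned unchanged.  Raises
    :class:`RemeshError` on infeasible bounds (``l_max < 2 * l_min`` can
    oscillate) or when the manifold would be destroyed.
    """
    if not (0 < l_min < l_max):
        raise ValueError("need 0 < l_min < l_max")
    if l_max < 2.0 * l_min:
        raise RemeshError("infeasible bounds: bisection of a long edge would undershoot l_min")
    lengths = mesh.edge_lengths()
    if lengths.min() >= l_min and lengths.max() <= l_max:
        return mesh.copy()

    vol0 = mesh.signed_volume()
    verts = [np.asarray(v, dtype=float) for v in mesh.vertices]
    faces = [tuple(int(i) for i in f) for f in mesh.faces]
    for _ in range(_MAX_PASSES):
        changed = _split_long_edges(verts, faces, l_max)
        changed |= _collapse_short_edges(verts, faces, l_min)
        work = TriMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64),
                       mesh.frame_index, mesh.instance_id)
        if not work.is_closed() or work.euler_characteristic() != 2:
            raise RemeshError("remeshing destroyed the closed manifold")
        _tangential_smooth(work)
        verts = [np.asarray(v, dtype=float) for v in work.vertices]
        faces = [tuple(int(i) for i in f) for f in work.faces]
        if not changed:
            break
        l = work.edge_lengths()
        if l.min() >= l_min * (1 - _EPS) and l.max() <= l_max * (1 + _EPS):
            break

    out = TriMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64),
                  mesh.frame_index, mesh.instance_id)
    l = out.edge_lengths()
    if l.max() > l_max * (1 + _EPS):
        raise RemeshError("could not reduce all edges below l_max")
    # restore enclosed volume (smoothing shrinks convex regions slightly)
    vol1 = out.signed_volume()
    if vol1 > 0 and vol0 > 0 and abs(vol1 - vol0) / vol0 > 1e-6:
        c = out.centroid()
        out.vertices = c + (out.vertices - c) * (vol0 / vol1) ** (1.0 / 3.0)
    try:
        out.validate()
    except InvalidMeshError as exc:  # e.g. a crushed region inverted itself
        raise RemeshError(f"result failed validation: {exc}") from exc
    return out
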