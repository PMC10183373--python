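"""Iterative active-mesh evolution to steady state.

Vertices take explicit-Euler steps along the sum of image, intrinsic and
(optionally) steric forces, with per-vertex step capping for stability and
periodic remeshing to keep the triangulation well conditioned.  A mesh
counts as converged when the maximum vertex displacement stays below a
tolerance for a sustained window of iterations; meshes that instead shrink
away (no steady state on their target) are removed by the small-volume
filter, which doubles as a false-positive filter for spurious seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np

from .energies import (
    DeformParams,
    gradient_energy_force,
    intensity_force,
    intrinsic_forces,
)
from .errors import DeformationError, DegenerateVertexError, RemeshError
from .mesh import TriMesh, points_inside, vertex_normals
from .remesh import remesh
from .volume import Volume

__all__ = ["DeformResult", "deform", "deform_cohort", "steric_forces", "filter_small"]

#: default minimum surviving volume: a ball of 1.5 µm radius
DEFAULT_V_MIN = 4.0 / 3.0 * np.pi * 1.5 ** 3


@dataclass
class DeformResult:
    """Outcome of evolving one mesh."""

    mesh: TriMesh
    converged: bool
    iterations_used: int
    final_max_displacement: float
    volume: float


def steric_forces(mesh: TriMesh, others: list[TriMesh], strength: float = 1.0) -> np.ndarray:
    """Repulsion pushing penetrating vertices back out of neighbour meshes.

    A vertex of ``mesh`` lying inside any mesh in ``others`` receives a
    force along its own reversed outward normal, with magnitude
    ``strength`` times a penetration-depth estimate (distance to the
    neighbour's nearest vertex).  Non-penetrating vertices feel nothing.
    """
    f = np.zeros_like(mesh.vertices)
    if not others:
        return f
    normals = None
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    for other in others:
        olo, ohi = other.vertices.min(axis=0), other.vertices.max(axis=0)
        if np.any(ohi < lo) or np.any(olo > hi):
            continue  # bounding boxes disjoint: no possible penetration
        if normals is None:
            normals = vertex_normals(mesh)
        inside = points_inside(other, mesh.vertices)
        if not inside.any():
            continue
        pen = mesh.vertices[inside]
        d = np.linalg.norm(pen[:, None, :] - other.vertices[None, :, :], axis=2).min(axis=1)
        f[inside] -= strength * d[:, None] * normals[inside]
    return f


def _image_force(mode: str, mesh: TriMesh, I: Volume, params: DeformParams,
                 normals: np.ndarray) -> np.ndarray:
    if params.w_img == 0.0:
        return np.zeros_like(mesh.vertices)
    if mode == "gradient":
        return gradient_energy_force(I, mesh.vertices, normals, params)
    if mode == "intensity":
        return intensity_force(I, mesh.vertices, normals, params)
    raise ValueError(f"unknown energy mode {mode!r}")


def _step(mesh: TriMesh, I: Volume, mode: str, params: DeformParams,
          others: list[TriMesh], steric_strength: float) -> float:
    """One explicit-Euler update in place; returns max displacement (µm).

    When ``others`` are present, steric repulsion resolves any existing
    penetration, and a no-entry guard reverts vertices whose trial
    position would land inside a neighbour mesh — contacts then settle
    (blocked vertices stop moving) instead of oscillating.
    """
    normals = vertex_normals(mesh)
    force = _image_force(mode, mesh, I, params, normals)
    force = force + intrinsic_forces(mesh, params.alpha, params.beta)
    if others:
        force = force + steric_forces(mesh, others, steric_strength)
    disp = params.step_size * force
    cap = params.max_step_px * min(I.spacing)
    norms = np.linalg.norm(disp, axis=1)
    over = norms > cap
    if over.any():
        disp[over] *= (cap / norms[over])[:, None]
    trial = mesh.vertices + disp
    if others:
        lo, hi = trial.min(axis=0), trial.max(axis=0)
        for other in others:
            olo = other.vertices.min(axis=0)
            ohi = other.vertices.max(axis=0)
            if np.any(ohi < lo) or np.any(olo > hi):
                continue
            blocked = points_inside(other, trial)
            if blocked.any():
                trial[blocked] = mesh.vertices[blocked]
    moved = trial - mesh.vertices
    mesh.vertices = trial
    return float(np.linalg.norm(moved, axis=1).max())


def deform(mesh: TriMesh, I: Volume, energy_mode: str = "gradient",
           params: DeformParams | None = None,
           others: list[TriMesh] | None = None,
           steric_strength: float = 1.0) -> DeformResult:
    """Evolve one mesh to steady state on image ``I``.

    ``energy_mode`` selects the image coupling: ``"gradient"`` (edge
    attraction, filled bright objects) or ``"intensity"`` (bright-sheet
    attraction; combine with negative ``w_img`` for distance transforms).
    Meshes in ``others`` act as static steric obstacles.

    Deterministic: identical inputs yield identical trajectories.
    """
    params = params or DeformParams()
    mesh.validate()
    work = mesh.copy()
    others = list(others) if others else []
    h = min(I.spacing)
    window: deque = deque(maxlen=params.convergence_window)
    converged = False
    it = 0
    last_disp = np.inf
    v_collapse = (0.5 * h) ** 3  # sub-voxel: the mesh has shrunk away
    for it in range(1, params.max_iters + 1):
        try:
            last_disp = _step(work, I, energy_mode, params, others, steric_strength)
        except DegenerateVertexError:
            break  # collapsed onto itself; reported unconverged and tiny
        window.append(last_disp)
        if len(window) == params.convergence_window and max(window) < params.tol:
            converged = True
            break
        if work.volume() < v_collapse:
            break
        if params.remesh_every and it % params.remesh_every == 0:
            try:
                work = remesh(work, params.l_min_px * h, params.l_max_px * h)
            except RemeshError as exc:
                raise DeformationError(f"remeshing failed at iteration {it}: {exc}",
                                       last_mesh=work) from exc
            window.clear()
    return DeformResult(mesh=work, converged=converged, iterations_used=it,
                        final_max_displacement=last_disp, volume=work.volume())


def _occupancy(works: list[TriMesh], I: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Bit-packed voxel occupancy per mesh.

    Returns ``(core, dilated)``: bit i set on voxels inside mesh i, and
    the same dilated by one voxel.  The dilated grid drives the no-entry
    guard (contacts settle with a small safety gap); the core grid
    detects genuine penetration.
    """
    from .mesh import binarize  # local import avoids a cycle at module load

    core = np.zeros(I.shape, dtype=np.uint32)
    dil = np.zeros(I.shape, dtype=np.uint32)
    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1, 1, :] = struct[1, :, 1] = struct[:, 1, 1] = True
    from scipy.ndimage import binary_dilation
    for i, m in enumerate(works):
        solid = binarize(m, I).data.astype(bool)
        core |= np.uint32(1 << i) * solid.astype(np.uint32)
        dil |= np.uint32(1 << i) * binary_dilation(solid, struct).astype(np.uint32)
    return core, dil


def _blocked(occ: np.ndarray, I: Volume, pts: np.ndarray, self_bit: int) -> np.ndarray:
    idx = np.round(I.world_to_index(pts)).astype(int)
    idx = np.clip(idx, 0, np.asarray(I.shape) - 1)
    vals = occ[idx[:, 0], idx[:, 1], idx[:, 2]]
    return (vals & ~np.uint32(self_bit)) != 0


def deform_cohort(meshes: list[TriMesh], I: Volume, energy_mode: str = "intensity",
                  params: DeformParams | None = None, steric: bool = True,
                  steric_strength: float = 1.0,
                  occupancy_refresh: int = 2) -> list[DeformResult]:
    """Evolve several meshes in lockstep with mutual steric exclusion.

    All meshes advance one iteration at a time.  Mutual exclusion uses a
    shared voxel-occupancy grid (each mesh rasterized and dilated by one
    voxel, refreshed every ``occupancy_refresh`` iterations): a vertex
    whose trial position lands on a voxel owned by another mesh does not
    move, so contacts settle deterministically instead of oscillating.
    Each mesh freezes once its own convergence window closes.
    """
    params = params or DeformParams()
    if len(meshes) > 32:
        raise ValueError("cohort limited to 32 meshes (occupancy bit grid)")
    works = [m.copy() for m in meshes]
    for m in works:
        m.validate()
    h = min(I.spacing)
    windows = [deque(maxlen=params.convergence_window) for _ in works]
    done = [False] * len(works)
    conv = [False] * len(works)
    iters = [0] * len(works)
    last = [np.inf] * len(works)
    occ = _occupancy(works, I) if steric and len(works) > 1 else None
    for it in range(1, params.max_iters + 1):
        if all(done):
            break
        if occ is not None and it % occupancy_refresh == 0:
            occ = _occupancy(works, I)
        core, dil = occ if occ is not None else (None, None)
        for i, m in enumerate(works):
            if done[i]:
                continue
            try:
                normals = vertex_normals(m)
            except DegenerateVertexError:
                done[i] = True
                continue
            force = _image_force(energy_mode, m, I, params, normals)
            force = force + intrinsic_forces(m, params.alpha, params.beta)
            cur_in = None
            if occ is not None:
                cur_in = _blocked(core, I, m.vertices, 1 << i)
                if cur_in.any():  # genuine penetration: exact repulsion
                    force = force + steric_forces(
                        m, [works[j] for j in range(len(works)) if j != i],
                        steric_strength)
            disp = params.step_size * force
            cap = params.max_step_px * h
            norms = np.linalg.norm(disp, axis=1)
            over = norms > cap
            if over.any():
                disp[over] *= (cap / norms[over])[:, None]
            trial = m.vertices + disp
            if occ is not None:
                hold = _blocked(dil, I, trial, 1 << i) & ~cur_in
                if hold.any():
                    trial[hold] = m.vertices[hold]
            moved = trial - m.vertices
            m.vertices = trial
            last[i] = float(np.linalg.norm(moved, axis=1).max())
            iters[i] = it
            windows[i].append(last[i])
            if len(windows[i]) == params.convergence_window and max(windows[i]) < params.tol:
                done[i] = True
                conv[i] = True
            elif m.volume() < (0.5 * h) ** 3:
                done[i] = True
        if params.remesh_every and it % params.remesh_every == 0:
            for i, m in enumerate(works):
                if done[i]:
                    continue
                try:
                    works[i] = remesh(m, params.l_min_px * h, params.l_max_px * h)
                except (RemeshError, DegenerateVertexError):
                    # a crushed or collapsing member stops evolving; it is
                    # reported unconverged and typically removed by the
                    # small-volume filter
                    done[i] = True
                    continue
                windows[i].clear()
    return [DeformResult(mesh=m, converged=c, iterations_used=n,
                         final_max_displacement=l, volume=m.volume())
            for m, c, n, l in zip(works, conv, iters, last)]


def filter_small(results: list[DeformResult], v_min: float = DEFAULT_V_MIN):
    """Partition results into (kept, removed) by enclosed volume >= v_min.

    Shrunken meshes — those that never found a steady state on their
    target — fall below the threshold and are removed; this is the
    false-positive filter for spurious seeds.
    """
    kept = [r for r in results if r.volume >= v_min]
    removed = [r for r in results if r.volume < v_min]
    return kept, removed
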