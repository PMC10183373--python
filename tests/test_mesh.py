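"""Mesh construction, raycast initialisation, voxelization, geometry."""

import numpy as np
import pytest

from actimesh import (
    SphereSet,
    TriMesh,
    Volume,
    binarize,
    bounding_box,
    make_icosphere,
    points_inside,
    raycast_from_region,
    raycast_from_spheres,
    remesh,
    vertex_normals,
)
from actimesh.errors import InvalidGeometryError, InvalidMeshError, RemeshError

from conftest import digitized_ball


class TestIcosphere:
    @pytest.mark.parametrize("s", [0, 1, 2])
    def test_combinatorics(self, s):
        m = make_icosphere((1.0, -2.0, 3.0), 5.0, s)
        assert m.n_faces == 20 * 4 ** s
        assert m.is_closed()
        assert m.euler_characteristic() == 2
        if s == 0:
            assert m.n_vertices == 12
            assert len(m.edges_unique()) == 30

    def test_vertices_on_sphere(self):
        m = make_icosphere((1.0, 2.0, 3.0), 7.5, 3)
        d = np.linalg.norm(m.vertices - [1.0, 2.0, 3.0], axis=1)
        assert np.allclose(d, 7.5, atol=1e-12)

    def test_outward_winding(self):
        assert make_icosphere((0, 0, 0), 2.0, 2).signed_volume() > 0

    @pytest.mark.parametrize("radius", [0.0, -1.0])
    def test_bad_radius(self, radius):
        with pytest.raises(ValueError):
            make_icosphere((0, 0, 0), radius, 1)


class TestVertexNormals:
    def test_unit_length_and_outward_on_sphere(self):
        c = np.array([2.0, 1.0, -1.0])
        m = make_icosphere(c, 4.0, 2)
        n = vertex_normals(m)
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)
        radial = (m.vertices - c) / np.linalg.norm(m.vertices - c, axis=1, keepdims=True)
        assert np.all(np.einsum("ij,ij->i", n, radial) > 0.99)

    def test_outward_on_random_convex(self, rng):
        m = make_icosphere((0, 0, 0), 1.0, 2)
        m.vertices = m.vertices * (1.0 + 0.2 * rng.random((m.n_vertices, 1)))
        n = vertex_normals(m)
        assert np.all(np.einsum("ij,ij->i", n, m.vertices) > 0)

    def test_translation_invariant(self):
        m = make_icosphere((0, 0, 0), 3.0, 2)
        n0 = vertex_normals(m)
        n1 = vertex_normals(m.translated([10.0, -5.0, 2.0]))
        assert np.allclose(n0, n1, atol=1e-12)


class TestRaycastFromSpheres:
    def test_single_sphere(self):
        ss = SphereSet([((1.0, 2.0, 3.0), 4.0)])
        m = raycast_from_spheres(ss, 2)
        d = np.linalg.norm(m.vertices - [1.0, 2.0, 3.0], axis=1)
        assert np.allclose(d, 4.0, atol=1e-9)
        assert m.is_closed() and m.euler_characteristic() == 2

    def test_matches_bisection_oracle(self, rng):
        """Vertex distances equal an independent inside-union bisection."""
        for _ in range(20):
            k = rng.integers(1, 4)
            centers = [rng.normal(0, 1, 3)]
            radii = [rng.uniform(1.5, 3.0)]
            for _ in range(k - 1):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                centers.append(centers[-1] + u * radii[-1] * rng.uniform(0.2, 0.9))
                radii.append(rng.uniform(1.0, 2.5))
            ss = SphereSet(list(zip(centers, radii)))
            mesh = raycast_from_spheres(ss, 1)
            c = np.mean(centers, axis=0)

            def inside(p):
                return any(np.linalg.norm(p - ci) <= ri for ci, ri in zip(centers, radii))

            for v in mesh.vertices[::7]:
                d = (v - c) / np.linalg.norm(v - c)
                # bracket the farthest boundary crossing by marching then bisect
                tmax = max(np.linalg.norm(ci - c) + ri for ci, ri in zip(centers, radii))
                ts = np.arange(0, tmax + 0.01, 0.01)
                ins = np.array([inside(c + t * d) for t in ts])
                last = np.flatnonzero(ins)[-1]
                lo, hi = ts[last], ts[last] + 0.01
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    lo, hi = (mid, hi) if inside(c + mid * d) else (lo, mid)
                assert np.linalg.norm(v - c) == pytest.approx(lo, abs=1e-6)

    def test_two_spheres_axis_vertex(self):
        r = 2.0
        ss = SphereSet([((0, 0, 0), r), ((0, 0, 1.5 * r), r)])
        m = raycast_from_spheres(ss, 3)
        # the farthest surface point along +z is the far pole of sphere 2
        top = m.vertices[np.argmax(m.vertices[:, 2])]
        assert top[2] == pytest.approx(1.5 * r + r, abs=0.05)

    def test_disconnected_union_rejected(self):
        with pytest.raises(ValueError):
            SphereSet([((0, 0, 0), 1.0), ((0, 0, 10.0), 1.0)])


class TestRaycastFromRegion:
    def test_digitized_ball_radius(self):
        region = Volume(digitized_ball(32, (16, 16, 16), 10), (1, 1, 1))
        m = raycast_from_region(region, 2)
        d = np.linalg.norm(m.vertices - 16.0, axis=1)
        assert 9.0 <= d.mean() <= 11.0
        assert m.is_closed() and m.signed_volume() > 0

    def test_single_voxel_region(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[4, 4, 4] = True
        m = raycast_from_region(Volume(data, (1, 1, 1)), 1)
        assert np.all(np.abs(m.vertices - 4.0) <= 0.5 + 1e-9)

    def test_empty_region(self):
        with pytest.raises(ValueError):
            raycast_from_region(Volume(np.zeros((8, 8, 8), bool), (1, 1, 1)), 1)

    def test_com_outside_region(self):
        shell = digitized_ball(32, (16, 16, 16), 12) & ~digitized_ball(32, (16, 16, 16), 9)
        with pytest.raises(InvalidGeometryError):
            raycast_from_region(Volume(shell, (1, 1, 1)), 1)


class TestBinarize:
    def test_ball_volume(self, unit_grid):
        g = unit_grid(40)
        m = make_icosphere((20, 20, 20), 10.0, 3)
        count = binarize(m, g).data.sum()
        analytic = 4 / 3 * np.pi * 1000
        assert abs(count - analytic) / analytic < 0.05

    def test_tiny_mesh_between_centers(self, unit_grid):
        g = unit_grid(8)
        m = make_icosphere((3.5, 3.5, 3.5), 0.3, 1)
        assert binarize(m, g).data.sum() == 0

    def test_roundtrip_with_raycast(self):
        # vertices land on boundary-voxel centres, so the mesh sits about
        # half a voxel inside the digitized ball; with r = 20 that shell
        # is well under 10% of the volume
        ball = digitized_ball(48, (24, 24, 24), 20)
        region = Volume(ball, (1, 1, 1))
        m = raycast_from_region(region, 3)
        recovered = binarize(m, Volume(np.zeros((48, 48, 48)), (1, 1, 1))).data.astype(bool)
        assert (recovered & ball).sum() >= 0.9 * ball.sum()

    def test_open_mesh_rejected(self, unit_grid):
        m = make_icosphere((16, 16, 16), 5.0, 1)
        open_mesh = TriMesh(m.vertices, m.faces[:-1])
        with pytest.raises(InvalidMeshError):
            binarize(open_mesh, unit_grid())

    def test_resolution_consistency(self):
        m = make_icosphere((10, 10, 10), 6.0, 3)
        coarse = binarize(m, Volume(np.zeros((20, 20, 20)), (1, 1, 1)))
        fine = binarize(m, Volume(np.zeros((40, 40, 40)), (0.5, 0.5, 0.5)))
        v1 = coarse.data.sum() * coarse.voxel_volume
        v2 = fine.data.sum() * fine.voxel_volume
        assert abs(v1 - v2) / v2 < 0.02

    def test_points_inside_agrees_with_binarize(self, unit_grid, rng):
        g = unit_grid(24)
        m = make_icosphere((12, 12, 12), 7.0, 2)
        vox = binarize(m, g).data.astype(bool)
        pts = rng.uniform(2, 22, size=(200, 3))
        inside = points_inside(m, pts)
        for p, flag in zip(pts, inside):
            near = tuple(np.round(p).astype(int))
            if abs(np.linalg.norm(p - 12) - 7.0) > 1.5:  # away from the surface
                assert bool(vox[near]) == bool(flag)


class TestBoundingBox:
    def test_icosphere_box(self):
        lo, hi = bounding_box(make_icosphere((5, 5, 5), 2.0, 2))
        assert np.allclose(lo, 3.0, atol=1e-9) and np.allclose(hi, 7.0, atol=1e-9)

    def test_translation_equivariance(self):
        m = make_icosphere((0, 0, 0), 3.0, 1)
        lo, hi = bounding_box(m)
        lo2, hi2 = bounding_box(m.translated([1, 2, 3]))
        assert np.allclose(lo2, lo + [1, 2, 3]) and np.allclose(hi2, hi + [1, 2, 3])

    def test_degenerate_triangle(self):
        m = TriMesh(np.array([[0.0, 0, 0], [1, 2, 0], [0, 1, 3]]), np.array([[0, 1, 2]]))
        lo, hi = bounding_box(m)
        assert np.allclose(lo, [0, 0, 0]) and np.allclose(hi, [1, 2, 3])


class TestRemesh:
    def test_conforming_unchanged(self):
        m = make_icosphere((0, 0, 0), 5.0, 2)
        lengths = m.edge_lengths()
        out = remesh(m, lengths.min() * 0.4, lengths.max() * 1.1)
        assert out.n_vertices == m.n_vertices
        assert np.allclose(out.vertices, m.vertices)

    def test_pulled_vertex_resolved(self):
        m = make_icosphere((0, 0, 0), 5.0, 2)
        l_max = 2.0
        m.vertices[0] *= 3.0
        out = remesh(m, 0.6, l_max)
        assert out.edge_lengths().max() <= l_max * 1.3
        assert out.is_closed() and out.euler_characteristic() == 2

    def test_volume_preserved(self):
        m = make_icosphere((0, 0, 0), 5.0, 2)
        out = remesh(m, 0.5, 1.2)  # forces splits
        assert abs(out.volume() - m.volume()) / m.volume() < 0.02

    def test_infeasible_bounds(self):
        m = make_icosphere((0, 0, 0), 5.0, 2)
        with pytest.raises(RemeshError):
            remesh(m, 1.0, 1.5)  # l_max < 2 l_min oscillates

    def test_bad_arguments(self):
        m = make_icosphere((0, 0, 0), 5.0, 1)
        with pytest.raises(ValueError):
            remesh(m, 2.0, 1.0)
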