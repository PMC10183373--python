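"""Image energies, forces, stencils and intrinsic mesh forces."""

import numpy as np
import pytest

from actimesh import (
    DeformParams,
    KernelSpec,
    TriMesh,
    Volume,
    gaussian_derivative_kernel,
    gradient_energy_force,
    intensity_force,
    intrinsic_forces,
    make_icosphere,
    perpendicular_gradient_energy,
    perpendicular_intensity_energy,
    sample_intensity,
    vertex_normals,
)


def step_volume(n=32, edge=16, axis=2):
    """Binary step along one axis: 0 below `edge`, 1 at and above."""
    data = np.zeros((n, n, n))
    sl = [slice(None)] * 3
    sl[axis] = slice(edge, None)
    data[tuple(sl)] = 1.0
    return Volume(data, (1, 1, 1))


class TestKernel:
    def test_center_zero_and_antisymmetric(self):
        k = gaussian_derivative_kernel(2.0, 5)
        c = k.coefficients
        assert c[5] == 0.0
        assert np.allclose(c, -c[::-1])

    def test_closed_form_values(self):
        sigma, w = 2.0, 5
        k = gaussian_derivative_kernel(sigma, w)
        for i in range(-w, w + 1):
            expected = -i / (np.sqrt(2 * np.pi) * sigma ** 3) * np.exp(-i * i / (2 * sigma * sigma))
            assert k.coefficients[i + w] == pytest.approx(expected, rel=1e-12)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gaussian_derivative_kernel(0.0, 5)
        with pytest.raises(ValueError):
            gaussian_derivative_kernel(2.0, 0)


class TestSampleIntensity:
    def test_voxel_center_exact(self, rng):
        data = rng.random((8, 8, 8))
        v = Volume(data, (1, 1, 1))
        assert sample_intensity(v, (3.0, 4.0, 5.0)) == pytest.approx(data[3, 4, 5])

    def test_midpoint_mean(self, rng):
        data = rng.random((8, 8, 8))
        v = Volume(data, (1, 1, 1))
        got = sample_intensity(v, (3.5, 4.0, 5.0))
        assert got == pytest.approx(0.5 * (data[3, 4, 5] + data[4, 4, 5]))

    def test_linear_ramp_exact(self, rng):
        idx = np.arange(16)
        data = 2.0 * idx[None, None, :] + 0.5 * idx[:, None, None] + 3.0
        v = Volume(data.astype(float), (1, 1, 1))
        pts = rng.uniform(0.0, 15.0, size=(50, 3))
        expected = 2.0 * pts[:, 2] + 0.5 * pts[:, 0] + 3.0
        assert np.allclose(sample_intensity(v, pts), expected, atol=1e-9)

    def test_out_of_bounds_clamped(self):
        data = np.arange(8, dtype=float)[None, None, :] * np.ones((8, 8, 8))
        v = Volume(data, (1, 1, 1))
        assert sample_intensity(v, (4.0, 4.0, 100.0)) == pytest.approx(7.0)
        assert sample_intensity(v, (4.0, 4.0, -100.0)) == pytest.approx(0.0)

    def test_anisotropic_spacing(self):
        data = np.arange(8, dtype=float)[:, None, None] * np.ones((8, 8, 8))
        v = Volume(data, (2.0, 1.0, 1.0))
        assert sample_intensity(v, (5.0, 3.0, 3.0)) == pytest.approx(2.5)


class TestGradientEnergy:
    def test_uniform_zero(self):
        v = Volume(np.full((16, 16, 16), 3.7), (1, 1, 1))
        e = perpendicular_gradient_energy(v, (8.0, 8.0, 8.0), (0.0, 0.0, 1.0))
        assert e == pytest.approx(0.0, abs=1e-24)

    def test_nonpositive(self, rng):
        v = Volume(rng.random((16, 16, 16)), (1, 1, 1))
        pts = rng.uniform(2, 14, size=(30, 3))
        n = rng.normal(size=(30, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        assert np.all(perpendicular_gradient_energy(v, pts, n) <= 1e-15)

    def test_step_edge_extremum_at_edge(self):
        v = step_volume(edge=16)
        n = (0.0, 0.0, 1.0)
        offsets = np.arange(10.0, 21.5, 0.5)
        es = [perpendicular_gradient_energy(v, (16.0, 16.0, x), n) for x in offsets]
        # intensity jumps between centres 15 and 16: |E| max at x = 15.5
        assert offsets[int(np.argmin(es))] == pytest.approx(15.5, abs=0.5)


class TestGradientForce:
    def test_uniform_zero(self):
        v = Volume(np.full((16, 16, 16), 2.0), (1, 1, 1))
        f = gradient_energy_force(v, (8.0, 8.0, 8.0), (0.0, 0.0, 1.0), DeformParams())
        assert np.allclose(f, 0.0, atol=1e-18)

    def test_pulled_toward_ball_edge(self):
        from scipy.ndimage import gaussian_filter

        zz, yy, xx = np.meshgrid(*[np.arange(40)] * 3, indexing="ij")
        ball = (((zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2) <= 100).astype(float)
        v = Volume(gaussian_filter(ball, 1.5), (1, 1, 1))
        params = DeformParams(w_img=1.0)
        # node 3 px inside the edge, outward normal +x
        f = gradient_energy_force(v, (20.0, 20.0, 27.0), (0.0, 0.0, 1.0), params)
        assert f[2] > 0

    def test_linear_in_weight(self, rng):
        v = Volume(rng.random((16, 16, 16)), (1, 1, 1))
        x, n = (8.0, 8.0, 8.0), (0.0, 1.0, 0.0)
        f_pos = gradient_energy_force(v, x, n, DeformParams(w_img=3.0))
        f_neg = gradient_energy_force(v, x, n, DeformParams(w_img=-3.0))
        assert np.allclose(f_pos, -f_neg, atol=1e-15)

    def test_parallel_to_normal(self, rng):
        v = Volume(rng.random((16, 16, 16)), (1, 1, 1))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        f = gradient_energy_force(v, (8.0, 8.0, 8.0), n, DeformParams(w_img=2.0))
        cross = np.cross(f, n)
        assert np.linalg.norm(cross) < 1e-12


class TestIntensityEnergy:
    def test_uniform_gives_minus_value(self):
        v = Volume(np.full((16, 16, 16), 4.2), (1, 1, 1))
        e = perpendicular_intensity_energy(v, (8.0, 8.0, 8.0), (0.0, 0.0, 1.0))
        assert e == pytest.approx(-4.2)

    def test_bright_plane_minimum_on_plane(self):
        data = np.zeros((32, 32, 32))
        data[:, :, 16] = 1.0
        v = Volume(data, (1, 1, 1))
        offsets = np.arange(12.0, 20.5, 0.5)
        es = [perpendicular_intensity_energy(v, (16.0, 16.0, x), (0.0, 0.0, 1.0))
              for x in offsets]
        assert offsets[int(np.argmin(es))] == pytest.approx(16.0, abs=0.5)

    def test_linearity_in_intensity(self, rng):
        data = rng.random((16, 16, 16))
        e1 = perpendicular_intensity_energy(Volume(data, (1, 1, 1)), (8.0, 8.0, 8.0), (0, 0, 1.0))
        e2 = perpendicular_intensity_energy(Volume(2 * data, (1, 1, 1)), (8.0, 8.0, 8.0), (0, 0, 1.0))
        assert e2 == pytest.approx(2 * e1)


class TestIntensityForce:
    def test_uniform_zero(self):
        v = Volume(np.full((16, 16, 16), 9.0), (1, 1, 1))
        f = intensity_force(v, (8.0, 8.0, 8.0), (0.0, 0.0, 1.0), DeformParams(w_img=1.0))
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_attracted_to_bright_plane(self):
        data = np.zeros((32, 32, 32))
        data[:, :, 20] = 1.0
        v = Volume(data, (1, 1, 1))
        # node 2 px below the plane, normal pointing at it
        f = intensity_force(v, (16.0, 16.0, 18.0), (0.0, 0.0, 1.0), DeformParams(w_img=1.0))
        assert f[2] > 0
        # negative weight repels instead
        f2 = intensity_force(v, (16.0, 16.0, 18.0), (0.0, 0.0, 1.0), DeformParams(w_img=-1.0))
        assert f2[2] < 0

    def test_flip_normal_on_ramp(self):
        data = np.arange(32, dtype=float)[None, None, :] * np.ones((32, 32, 32))
        v = Volume(data, (1, 1, 1))
        x = (16.0, 16.0, 16.0)
        f_up = intensity_force(v, x, (0.0, 0.0, 1.0), DeformParams(w_img=1.0))
        f_down = intensity_force(v, x, (0.0, 0.0, -1.0), DeformParams(w_img=1.0))
        # the force climbs the ramp regardless of which way n points
        assert f_up[2] > 0 and f_down[2] > 0
        assert f_up[2] == pytest.approx(f_down[2], rel=1e-12)

    def test_energy_force_consistency(self):
        """Integrating the force along n recovers -dE of the intensity energy.

        The force normalises by sum|k_i| while the energy normalises by
        sum G(u); the two differ by the fixed positive constant
        rho = sigma^2 * sum G / sum |i| G, computed here independently.
        """
        from scipy.ndimage import gaussian_filter

        sigma, w = 2.0, 5
        i = np.arange(-w, w + 1)
        g = np.exp(-(i ** 2) / (2 * sigma ** 2))
        rho = sigma ** 2 * g.sum() / np.abs(i * g).sum()

        data = np.zeros((48, 48, 48))
        data[24, 24, 24] = 1000.0
        v = Volume(gaussian_filter(data, 4.0), (1, 1, 1))
        n = np.array([0.0, 0.0, 1.0])
        params = DeformParams(w_img=1.0)
        a, b = 14.0, 22.0
        xs = np.arange(a, b + 0.05, 0.1)
        fs = [intensity_force(v, (24.0, 24.0, x), n, params)[2] for x in xs]
        work = np.trapezoid(fs, xs)
        e_a = perpendicular_intensity_energy(v, (24.0, 24.0, a), n)
        e_b = perpendicular_intensity_energy(v, (24.0, 24.0, b), n)
        assert work == pytest.approx(-rho * (e_b - e_a), rel=0.05)


def flat_grid_mesh(n=5):
    """Regular triangulated sheet in the x-y plane (not closed)."""
    verts = np.array([[0.0, j, i] for j in range(n) for i in range(n)])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriMesh(verts, np.asarray(faces))


class TestIntrinsicForces:
    def test_flat_grid_interior_zero(self):
        m = flat_grid_mesh(5)
        f = intrinsic_forces(m, alpha=1.0, beta=0.5)
        center = 2 * 5 + 2
        assert np.allclose(f[center], 0.0, atol=1e-12)

    def test_zero_weights(self):
        m = make_icosphere((0, 0, 0), 3.0, 1)
        assert np.allclose(intrinsic_forces(m, 0.0, 0.0), 0.0)

    def test_icosphere_shrinks_monotonically(self):
        m = make_icosphere((0, 0, 0), 5.0, 2)
        vols = [m.volume()]
        for _ in range(100):
            m.vertices = m.vertices + 0.1 * intrinsic_forces(m, alpha=1.0, beta=0.0)
            vols.append(m.volume())
        assert all(b < a for a, b in zip(vols, vols[1:]))

    def test_translation_invariant(self):
        m = make_icosphere((0, 0, 0), 3.0, 2)
        f0 = intrinsic_forces(m, 0.7, 0.3)
        f1 = intrinsic_forces(m.translated([5.0, -2.0, 1.0]), 0.7, 0.3)
        assert np.allclose(f0, f1, atol=1e-12)
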