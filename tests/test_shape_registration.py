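from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from cardax import polarity_stats as ps
from cardax import shape_registration as sr
from cardax import synthetic_data as sd
from cardax.io_formats import AxisSet, SurfaceMesh

from _oracles import polar_rotation_search, polar_rotation_sqrtm


def kabsch_residual(moving: np.ndarray, target: np.ndarray) -> float:
    """RMS residual after optimal rigid alignment (Procrustes distance)."""
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    U, _, Vt = np.linalg.svd(mc.T @ tc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return float(np.sqrt(np.mean(np.sum((mc @ R.T - tc) ** 2, axis=1))))


def _random_axes(n, lo, hi, seed):
    rng = np.random.default_rng(seed)
    return AxisSet.from_vectors(rng.uniform(lo, hi, size=(n, 3)),
                                rng.normal(size=(n, 3)))


class TestIntegrateVelocity:
    def test_zero_velocity_is_identity(self):
        phi = sr.integrate_velocity(np.zeros((8, 8, 8, 3)), (1, 1, 1))
        assert np.all(phi.disp == 0)

    def test_constant_velocity_is_translation(self):
        v = np.zeros((8, 8, 8, 3))
        v[...] = [1.5, -0.5, 2.0]
        phi = sr.integrate_velocity(v, (1, 1, 1))
        np.testing.assert_allclose(phi.disp, v, atol=1e-12)

    def test_linear_rotation_generator_matches_matrix_exponential(self):
        """v(x) = A x with A a scaled rotation generator: exp(v) = e^A x."""
        A = 0.1 * np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 0]])  # 90° generator
        n = 16
        grid = sr.DeformationField.identity((n, n, n), (1, 1, 1),
                                            origin=(-7.5, -7.5, -7.5))
        pts = grid.grid_points()
        v = pts @ A.T
        phi = sr.integrate_velocity(v, (1, 1, 1), origin=(-7.5, -7.5, -7.5),
                                    steps=16)
        eA = expm(A)
        # interior points whose orbit stays on-grid
        test = pts[4:-4, 4:-4, 4:-4].reshape(-1, 3)
        np.testing.assert_allclose(phi(test), test @ eA.T, atol=1e-6)

    def test_folding_map_rejected_with_location(self):
        phi = sr.DeformationField.from_affine(np.diag([-1.0, 1.0, 1.0]),
                                              np.zeros(3), (8, 8, 8), (1, 1, 1))
        with pytest.raises(sr.InvertibilityError, match="det"):
            phi.check_invertible()


class TestJacobian:
    def test_affine_field_exact(self):
        A = np.array([[1.2, 0.3, 0.0], [-0.1, 0.9, 0.2], [0.0, 0.1, 1.1]])
        phi = sr.DeformationField.from_affine(A, [1.0, 2.0, 3.0], (10, 10, 10),
                                              (1, 1, 1))
        pts = np.array([[4.2, 5.1, 3.3], [2.0, 2.0, 7.0]])
        J = sr.jacobian_at(phi, pts)
        np.testing.assert_allclose(J, np.broadcast_to(A, (2, 3, 3)), atol=1e-12)

    def test_boundary_points_flagged(self):
        phi = sr.DeformationField.identity((6, 6, 6), (1, 1, 1))
        with pytest.warns(UserWarning, match="one-sided"):
            sr.jacobian_at(phi, np.array([[0.2, 3.0, 3.0]]))

    def test_outside_domain_rejected(self):
        phi = sr.DeformationField.identity((6, 6, 6), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            sr.jacobian_at(phi, np.array([[10.0, 0.0, 0.0]]))


class TestPolarRotation:
    def test_pure_rotation_returned_unchanged(self):
        R = Rotation.from_euler("xyz", [30, -60, 100], degrees=True).as_matrix()
        np.testing.assert_allclose(sr.polar_rotation(R), R, atol=1e-12)

    def test_pure_stretch_gives_identity(self):
        np.testing.assert_allclose(sr.polar_rotation(np.diag([2.0, 1.0, 0.5])),
                                   np.eye(3), atol=1e-13)

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="det"):
            sr.polar_rotation(np.diag([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="det"):
            sr.polar_rotation(np.diag([1.0, 1.0, -2.0]))

    def test_matches_sqrtm_oracle_batch(self):
        """SVD polar factor equals J (JᵀJ)^(-1/2) on random det-positive J."""
        rng = np.random.default_rng(21)
        count = 0
        while count < 300:
            J = rng.normal(size=(3, 3))
            if np.linalg.det(J) <= 0.05:
                continue
            count += 1
            np.testing.assert_allclose(sr.polar_rotation(J),
                                       polar_rotation_sqrtm(J), atol=1e-6)

    def test_matches_procrustes_search_oracle(self):
        """Polar factor minimizes ||J − Q||_F over rotations (direct search)."""
        rng = np.random.default_rng(22)
        for _ in range(3):
            J = rng.normal(size=(3, 3))
            if np.linalg.det(J) <= 0:
                J = J @ np.diag([1, 1, -1])
            np.testing.assert_allclose(sr.polar_rotation(J),
                                       polar_rotation_search(J), atol=1e-5)

    def test_symmetric_positive_definite_remainder(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            J = rng.normal(size=(3, 3))
            if np.linalg.det(J) <= 0:
                J[:, 0] *= -1
            S = sr.polar_rotation(J).T @ J
            np.testing.assert_allclose(S, S.T, atol=1e-10)
            assert np.all(np.linalg.eigvalsh(S) > 0)


class TestTransportAxes:
    def test_identity_transport(self):
        axes = _random_axes(20, 2, 13, seed=1)
        phi = sr.DeformationField.identity((16, 16, 16), (1, 1, 1))
        out = sr.transport_axes(axes, phi)
        np.testing.assert_allclose(out.axes, axes.axes, atol=1e-12)
        np.testing.assert_allclose(out.positions, axes.positions, atol=1e-12)

    def test_rigid_rotation_rotates_axes_exactly(self):
        axes = _random_axes(40, -4, 4, seed=2)
        phi = sd.make_deformation("rotation", shape=(17, 17, 17),
                                  origin=(-8, -8, -8), angle_deg=35.0,
                                  axis=(1.0, 2.0, 0.5), center=(0, 0, 0))
        R = Rotation.from_rotvec(
            np.deg2rad(35.0) * np.array([1.0, 2.0, 0.5])
            / np.linalg.norm([1.0, 2.0, 0.5])).as_matrix()
        out = sr.transport_axes(axes, phi)
        from cardax.io_formats import sign_normalize
        np.testing.assert_allclose(out.axes, sign_normalize(axes.axes @ R.T),
                                   atol=1e-9)
        # pairwise angles preserved, E1 unchanged
        e_before = ps.orientation_stats(axes).e1
        e_after = ps.orientation_stats(out).e1
        assert abs(e_before - e_after) < 1e-12

    def test_pure_stretch_leaves_directions_unchanged(self):
        """The no-spurious-improvement property: stretch cannot change E1."""
        axes = _random_axes(60, 3, 12, seed=3)
        phi = sd.make_deformation("stretch", shape=(16, 16, 16),
                                  factors=(2.0, 1.0, 0.5))
        out = sr.transport_axes(axes, phi)
        np.testing.assert_allclose(out.axes, axes.axes, atol=1e-12)
        assert abs(ps.orientation_stats(out).e1
                   - ps.orientation_stats(axes).e1) < 1e-12

    def test_round_trip_through_inverse(self):
        """Transport through exp(v) then exp(−v) returns axes within 1e-3 rad."""
        n = 32
        v = sd._bandlimited_velocity((n, n, n), (1, 1, 1), (0, 0, 0),
                                     amplitude=1.5, max_freq=1, seed=5)
        phi = sr.integrate_velocity(v, (1, 1, 1), mode="grid-wrap")
        phi_inv = sr.integrate_velocity(-v, (1, 1, 1), mode="grid-wrap")
        axes = _random_axes(30, 8, 24, seed=6)
        back = sr.transport_axes(sr.transport_axes(axes, phi), phi_inv)
        dots = np.clip(np.abs(np.sum(back.axes * axes.axes, axis=1)), 0, 1)
        assert np.arccos(dots).max() < 1e-3
        assert np.linalg.norm(back.positions - axes.positions, axis=1).max() < 0.05

    def test_positions_outside_domain_rejected(self):
        axes = _random_axes(3, 40, 50, seed=7)
        phi = sr.DeformationField.identity((8, 8, 8), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            sr.transport_axes(axes, phi)


class TestBuildTemplate:
    def _sphere(self, unit_sphere, noise, seed, rotate=None, shift=None):
        rng = np.random.default_rng(seed)
        v = unit_sphere.vertices.copy()
        if noise:
            v = v + rng.normal(0, noise, v.shape)
        if rotate is not None:
            v = v @ rotate.T
        if shift is not None:
            v = v + shift
        return SurfaceMesh(v, unit_sphere.faces)

    def test_identical_envelopes_identity(self, unit_sphere):
        tpl = sr.build_template([unit_sphere] * 4)
        np.testing.assert_allclose(
            tpl.mesh.vertices,
            unit_sphere.vertices - unit_sphere.vertices.mean(axis=0), atol=1e-12)

    def test_rigidly_rotated_copies_congruent(self, unit_sphere):
        base = self._sphere(unit_sphere, noise=0.08, seed=0)
        R = Rotation.from_euler("zx", [73, -28], degrees=True).as_matrix()
        moved = self._sphere(unit_sphere, noise=0.08, seed=0, rotate=R,
                             shift=np.array([5.0, -2.0, 1.0]))
        tpl = sr.build_template([base, moved])
        # congruence: optimal rigid alignment to base leaves ~zero residual
        assert kabsch_residual(tpl.mesh.vertices, base.vertices) < 1e-9

    def test_noise_averaging_rms(self, unit_sphere):
        """Ten noisy spheres: radial RMS error of the template ≈ σ/√10."""
        sigma = 0.05
        envs = [self._sphere(unit_sphere, sigma, seed=s) for s in range(10)]
        tpl = sr.build_template(envs)
        radii = np.linalg.norm(tpl.mesh.vertices - tpl.mesh.vertices.mean(axis=0),
                               axis=1)
        rms = np.sqrt(np.mean((radii - 1.0) ** 2))
        assert rms == pytest.approx(sigma / np.sqrt(10), rel=0.2)

    def test_mismatched_vertex_counts_rejected(self, unit_sphere):
        import trimesh
        small = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(1))
        with pytest.raises(ValueError, match="vertex counts"):
            sr.build_template([unit_sphere, small])


class TestFieldIO:
    def test_round_trip(self, tmp_path):
        phi = sd.make_deformation("smooth-random", shape=(12, 12, 12),
                                  amplitude=1.0, seed=3)
        sr.save_field(phi, tmp_path / "f.tif", tmp_path / "f.json")
        back = sr.load_field(tmp_path / "f.tif", tmp_path / "f.json")
        np.testing.assert_allclose(back.disp, phi.disp, atol=1e-6)
        assert back.mode == phi.mode
        np.testing.assert_allclose(back.spacing, phi.spacing)
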