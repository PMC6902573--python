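"""Geometric primitives: circle/line fitting, slicing, projected angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from femver.errors import (
    DegenerateGeometryError,
    MissingLandmarkError,
    UndefinedProjectionError,
)
from femver.geometry import (
    Line3D,
    PlanarContour,
    RigidTransform,
    SurfaceModel,
    compute_knee_center,
    compute_pca_direction,
    fit_circle,
    fit_line_3d,
    outer_and_canal,
    plane_basis,
    projected_angle,
    signed_line_angle,
    slice_mesh,
)
from tests.conftest import rotation_matrix


def tube_mesh(outer_r, inner_r, height, n=64, rings=5):
    """Closed hollow tube along z (annular caps), a minimal two-loop fixture."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    zs = np.linspace(0.0, height, rings)
    verts, faces = [], []
    for radius in (outer_r, inner_r):
        base = len(verts)
        for z in zs:
            verts.extend(np.column_stack([radius * np.cos(t), radius * np.sin(t), np.full(n, z)]))
        for k in range(rings - 1):
            a0, b0 = base + k * n, base + (k + 1) * n
            i = np.arange(n)
            j = (i + 1) % n
            faces.extend(np.column_stack([a0 + i, a0 + j, b0 + i]))
            faces.extend(np.column_stack([b0 + i, a0 + j, b0 + j]))
    i = np.arange(n)
    j = (i + 1) % n
    off = rings * n
    for ring0 in (0, (rings - 1) * n):  # caps
        faces.extend(np.column_stack([ring0 + i, ring0 + j, off + ring0 + i]))
        faces.extend(np.column_stack([off + ring0 + i, ring0 + j, off + ring0 + j]))
    return SurfaceModel(np.asarray(verts), np.asarray(faces))


def cylinder_mesh(radius, height, n=64, rings=5):
    return tube_mesh(radius, radius * 0.25, height, n=n, rings=rings)


class TestFitCircle:
    def test_exact_circle(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        fit = fit_circle(np.column_stack([np.cos(t), np.sin(t)]))
        assert np.allclose(fit.center, [0, 0], atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)
        assert fit.rms == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cx=st_h.floats(-1e3, 1e3),
        cy=st_h.floats(-1e3, 1e3),
        r=st_h.floats(1e-3, 1e3),
    )
    def test_scale_free_exactness(self, cx, cy, r):
        """Any exact circle is recovered to relative precision (scale-free)."""
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
        fit = fit_circle(pts)
        scale = max(abs(cx), abs(cy), r, 1.0)
        assert np.allclose(fit.center, [cx, cy], atol=1e-8 * scale)
        assert fit.radius == pytest.approx(r, rel=1e-8)

    def test_three_point_circumcircle(self):
        fit = fit_circle([(0, 0), (2, 0), (1, 1)])
        assert np.allclose(fit.center, [1, 0], atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("pts", [[(0, 0), (1, 0), (2, 0)], [(0, 0), (1, 1)]])
    def test_degenerate(self, pts):
        with pytest.raises(DegenerateGeometryError):
            fit_circle(pts)


class TestFitLine3D:
    def test_exact_line(self):
        pts = [(0, 0, k) for k in range(11)]
        line = fit_line_3d(pts)
        assert np.allclose(np.abs(line.direction), [0, 0, 1], atol=1e-12)
        assert np.allclose(line.origin, [0, 0, 5], atol=1e-12)

    def test_noisy_line_direction(self):
        """80 points over 300 mm with 0.1 mm isotropic noise: direction
        within 0.1 degrees of truth."""
        rng = np.random.default_rng(7)
        d = np.array([1.0, 2.0, 5.0])
        d /= np.linalg.norm(d)
        t = np.linspace(0, 300, 80)
        pts = np.outer(t, d) + rng.normal(0, 0.1, (80, 3))
        line = fit_line_3d(pts)
        ang = np.degrees(np.arccos(np.clip(abs(line.direction @ d), 0, 1)))
        assert ang < 0.1

    def test_identical_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_line_3d([(1, 2, 3), (1, 2, 3)])


class TestPlaneBasisAndAngles:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_h.tuples(*[st_h.floats(-1, 1) for _ in range(3)]))
    def test_plane_basis_right_handed(self, n):
        n = np.asarray(n)
        if np.linalg.norm(n) < 1e-3:
            return
        e1, e2 = plane_basis(n)
        nn = n / np.linalg.norm(n)
        assert abs(e1 @ e2) < 1e-12
        assert np.allclose(np.cross(e1, e2), nn, atol=1e-12)

    def test_projected_angle_examples(self):
        z = Line3D([0, 0, 0], [0, 0, 1])
        assert projected_angle([1, 0], [1, 0], z) == pytest.approx(0.0)
        assert projected_angle([0, 1], [1, 0], z) == pytest.approx(90.0)
        assert projected_angle([1, 1, 5], [1, 0], z) == pytest.approx(45.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st_h.floats(-3, 3),
        b=st_h.floats(-3, 3),
        c=st_h.floats(-3, 3),
        d=st_h.floats(-3, 3),
    )
    def test_projected_angle_antisymmetric(self, a, b, c, d):
        u, v = np.array([a, b]), np.array([c, d])
        if np.linalg.norm(u) < 1e-3 or np.linalg.norm(v) < 1e-3:
            return
        z = Line3D([0, 0, 0], [0, 0, 1])
        a1 = projected_angle(u, v, z)
        a2 = projected_angle(v, u, z)
        if abs(abs(a1) - 180.0) > 1e-6:  # +-180 is the same angle
            assert a1 == pytest.approx(-a2, abs=1e-9)

    def test_projected_angle_parallel_to_axis(self):
        z = Line3D([0, 0, 0], [0, 0, 1])
        with pytest.raises(UndefinedProjectionError):
            projected_angle([0, 0, 4], [1, 0], z)

    def test_signed_line_angle_range_and_side(self):
        pca = np.array([1.0, 0.0])
        d = np.array([np.cos(np.radians(20)), np.sin(np.radians(20))])
        assert signed_line_angle(d, pca, "right") == pytest.approx(20.0)
        assert signed_line_angle(-d, pca, "right") == pytest.approx(20.0)
        assert signed_line_angle(d, pca, "left") == pytest.approx(-20.0)


class TestSliceMesh:
    def test_cylinder_circle_section(self):
        mesh = cylinder_mesh(1.0, 100.0)
        axis = Line3D([0, 0, 0], [0, 0, 1])
        contours = slice_mesh(mesh, axis, 50.0)
        outer, _ = outer_and_canal(contours)
        fit = fit_circle(outer.points)
        assert fit.radius == pytest.approx(1.0, rel=2e-3)
        # polygonal section area approaches pi r^2 (within 1% at >= 64 segments)
        assert outer.area() == pytest.approx(np.pi, rel=0.01)

    def test_station_beyond_extent(self):
        mesh = cylinder_mesh(1.0, 100.0)
        axis = Line3D([0, 0, 0], [0, 0, 1])
        assert slice_mesh(mesh, axis, 150.0) == []

    def test_hollow_tube_two_contours(self):
        mesh = tube_mesh(15.0, 8.0, 60.0)
        axis = Line3D([0, 0, 0], [0, 0, 1])
        contours = slice_mesh(mesh, axis, 30.0)
        assert len(contours) == 2
        outer, canal = outer_and_canal(contours)
        assert canal is not None
        assert fit_circle(outer.points).radius == pytest.approx(15.0, rel=2e-3)
        assert fit_circle(canal.points).radius == pytest.approx(8.0, rel=2e-3)

    def test_slice_at_ring_plane_is_robust(self):
        """A plane exactly through a vertex ring still yields a closed loop."""
        mesh = cylinder_mesh(1.0, 100.0)
        axis = Line3D([0, 0, 0], [0, 0, 1])
        contours = slice_mesh(mesh, axis, 25.0)  # rings at z = 0, 25, 50, ...
        assert contours and contours[0].closed


class TestLandmarkOps:
    def test_knee_center_midpoint(self, default_femur):
        model, _ = default_femur
        kc = compute_knee_center(model)
        expected = (model.landmark("MED_EPICONDYLE") + model.landmark("LAT_EPICONDYLE")) / 2
        assert np.allclose(kc, expected)

    def test_knee_center_arithmetic(self):
        m = SurfaceModel(
            np.eye(4, 3) * 30,
            [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]],
            {"MED_EPICONDYLE": [10, 0, 0], "LAT_EPICONDYLE": [20, 4, 0]},
        )
        assert np.allclose(compute_knee_center(m), [15, 2, 0])

    def test_missing_epicondyle(self):
        m = SurfaceModel(
            np.eye(4, 3),
            [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]],
            {"MED_EPICONDYLE": [10, 0, 0]},
        )
        with pytest.raises(MissingLandmarkError):
            compute_knee_center(m)

    def test_pca_direction_hand_projection(self):
        m = SurfaceModel(
            np.eye(4, 3),
            [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]],
            {"MED_POST_CONDYLE": [0, -20, 0], "LAT_POST_CONDYLE": [40, -20, 5]},
        )
        axis = Line3D([0, 0, 0], [0, 0, 1])
        # basis for n = z is (x, y): lat - med projects to +x
        v = compute_pca_direction(m, axis)
        assert np.allclose(v, [1, 0], atol=1e-12)

    def test_pca_coincident_condyles(self):
        m = SurfaceModel(
            np.eye(4, 3),
            [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]],
            {"MED_POST_CONDYLE": [1, 2, 0], "LAT_POST_CONDYLE": [1, 2, 9]},
        )
        with pytest.raises(DegenerateGeometryError):
            compute_pca_direction(m, Line3D([0, 0, 0], [0, 0, 1]))


class TestRigidTransform:
    def test_validation(self):
        with pytest.raises(DegenerateGeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection

    def test_compose_inverse(self):
        T = RigidTransform(rotation_matrix([1, 2, 3], 20.0), [4.0, -1.0, 2.0])
        I = T.compose(T.inverse())
        assert np.allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(I.translation, 0, atol=1e-12)

    def test_contour_validation(self):
        with pytest.raises(DegenerateGeometryError):
            PlanarContour(0.0, [(0, 0), (1, 1)])
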