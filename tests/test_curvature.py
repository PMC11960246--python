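"""Cylinder/circle fitting, patch isolation and signed radii of curvature."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cartmorph import (
    CohortConfig,
    CylinderFit,
    analytic_fixture,
    extract_elliptical_patch,
    fit_circle_in_plane,
    fit_cylinder,
    generate_base_surface,
    measure_roc,
    patch_dimensions,
    place_probe_points,
    probe_planes,
    select_posterior_articulating_surface,
)
from cartmorph.curvature import Plane, PlanarCircleFit
from cartmorph.synthetic import probe_truth


def _cylinder_points(radius=20.0, n=500, seed=0, noise=0.0, arc=2.0, height=40.0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(-arc / 2, arc / 2, n)
    z = rng.uniform(-height / 2, height / 2, n)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), z])
    return pts + rng.normal(0, noise, pts.shape)


class TestCylinderFit:
    def test_exact_cylinder_recovered(self):
        fit = fit_cylinder(_cylinder_points())
        assert fit.radius == pytest.approx(20.0, abs=1e-6)
        assert abs(abs(fit.axis_direction[2]) - 1.0) < 1e-6
        assert fit.rms_residual < 1e-9
        assert not fit.ill_conditioned

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_cylinder_radius_bounded(self, seed):
        fit = fit_cylinder(_cylinder_points(seed=seed, noise=0.1))
        assert fit.radius == pytest.approx(20.0, abs=0.1)

    def test_sphere_points_flagged_ill_conditioned(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(600, 3))
        pts = 20.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        fit = fit_cylinder(pts)
        assert fit.ill_conditioned

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cylinder(np.zeros((4, 3)))


class TestProbePlanes:
    CYL = CylinderFit(axis_point=np.zeros(3), axis_direction=np.array([0.0, 0.0, 1.0]),
                      radius=20.0, rms_residual=0.0)

    def test_closed_form_planes(self):
        ap, ml = probe_planes(self.CYL, np.array([20.0, 0.0, 5.0]))
        # AP plane: z = 5
        assert abs(abs(ap.normal[2]) - 1.0) < 1e-12
        assert ap.point[2] == pytest.approx(5.0)
        # ML plane: y = 0 (contains the z axis and the probe)
        assert abs(abs(ml.normal[1]) - 1.0) < 1e-12
        assert abs(float(ap.normal @ ml.normal)) < 1e-12

    def test_probe_on_axis_rejected(self):
        with pytest.raises(ValueError):
            probe_planes(self.CYL, np.array([0.0, 0.0, 3.0]))


class TestPatchDimensions:
    def test_printed_ellipse_axes(self):
        a, b = patch_dimensions(270.0, 1.70)
        assert round(a, 1) == 24.2
        assert round(b, 1) == 14.2

    def test_unit_circle(self):
        assert patch_dimensions(np.pi, 1.0) == pytest.approx((2.0, 2.0))

    @pytest.mark.parametrize("area,aspect", [(270.0, 1.7), (100.0, 1.0), (55.5, 2.3)])
    def test_inverse_identity(self, area, aspect):
        a, b = patch_dimensions(area, aspect)
        assert np.pi * (a / 2) * (b / 2) == pytest.approx(area, rel=1e-10)
        assert a / b == pytest.approx(aspect, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            patch_dimensions(-1.0, 1.5)
        with pytest.raises(ValueError):
            patch_dimensions(100.0, 0.5)


class TestCircleFit:
    def test_exact_circle_any_centre(self):
        fx = analytic_fixture("exact_circle_points", radius=5.0, n=40,
                              center=(3.0, -2.0, 7.0), normal=(0, 0, 1))
        plane = Plane(point=np.array([0.0, 0.0, 7.0]), normal=np.array([0.0, 0.0, 1.0]))
        res = fit_circle_in_plane(fx.points, plane)
        assert res.radius == pytest.approx(5.0, abs=1e-6)
        assert res.residual < 1e-9

    def test_collinear_points_flat(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
        fit = PlanarCircleFit().fit(pts)
        assert fit.flat_

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_arc_radius_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1.5, 200)
        pts = np.column_stack([25.6 * np.cos(t), 25.6 * np.sin(t)])
        pts += rng.normal(0, 0.05, pts.shape)
        fit = PlanarCircleFit().fit(pts)
        assert fit.radius_ == pytest.approx(25.6, abs=0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_sign_convention_under_random_orientation(self, seed):
        """Convex always positive, concave always negative, regardless of
        pose: points on a circle, probe on the circle, normal pointing away
        from (convex) or towards (concave) the centre."""
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=seed).as_matrix()
        centre = rng.normal(0, 50, 3)
        normal3 = R @ np.array([0.0, 0.0, 1.0])
        fx = analytic_fixture("exact_circle_points", radius=8.0, n=60,
                              center=centre, normal=normal3)
        plane = Plane(point=centre, normal=normal3)
        probe = fx.points[0]
        outward = (probe - centre) / 8.0
        convex = fit_circle_in_plane(fx.points, plane, probe_point=probe, probe_normal=outward)
        concave = fit_circle_in_plane(fx.points, plane, probe_point=probe, probe_normal=-outward)
        assert convex.signed_radius == pytest.approx(8.0, abs=1e-6)
        assert concave.signed_radius == pytest.approx(-8.0, abs=1e-6)


class TestPatchExtraction:
    def test_flat_plane_patch_area(self):
        xs = np.linspace(-25, 25, 80)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        from cartmorph import SurfaceMesh

        n = len(xs)
        verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + n, a + 1])
                faces.append([a + 1, a + n, a + n + 1])
        mesh = SurfaceMesh(verts, np.asarray(faces))
        axes = patch_dimensions(270.0, 1.7)
        patch, _, clipped = extract_elliptical_patch(
            mesh, np.zeros(3), axes, ap_direction=np.array([1.0, 0.0, 0.0]),
            probe_normal=np.array([0.0, 0.0, 1.0]),
        )
        from cartmorph import surface_area

        assert surface_area(patch) == pytest.approx(270.0, rel=0.02)
        assert not clipped

    def test_large_sphere_patch_area_small_distortion(self):
        fx = analytic_fixture("sphere_cap", radius=100.0, cap_angle_deg=30, n=120)
        probe = np.array([0.0, 0.0, 100.0])
        axes = patch_dimensions(270.0, 1.7)
        patch, _, _ = extract_elliptical_patch(
            fx.mesh, probe, axes, ap_direction=np.array([1.0, 0.0, 0.0]),
        )
        from cartmorph import surface_area

        assert surface_area(patch) == pytest.approx(270.0, rel=0.03)

    def test_probe_face_inside_patch(self, base_surface):
        probe = base_surface.vertices[base_surface.n_vertices // 2]
        patch, mask, _ = extract_elliptical_patch(
            base_surface, probe, patch_dimensions(100.0, 1.5),
            ap_direction=np.array([0.0, 1.0, 0.0]),
        )
        fc = base_surface.vertices[base_surface.faces].mean(axis=1)
        nearest_face = int(np.argmin(np.linalg.norm(fc - probe, axis=1)))
        assert mask[nearest_face]

    def test_boundary_clip_flagged(self, base_surface):
        # probe at the mesh corner: the ellipse must run off the sheet
        probe = base_surface.vertices[0]
        patch, _, clipped = extract_elliptical_patch(
            base_surface, probe, patch_dimensions(270.0, 1.7),
            ap_direction=np.array([0.0, 1.0, 0.0]),
        )
        assert clipped


class TestMeasureRoc:
    SPHERE_CYL = CylinderFit(axis_point=np.zeros(3),
                             axis_direction=np.array([0.0, 1.0, 0.0]),
                             radius=20.0, rms_residual=0.0)

    def test_sphere_ap_equals_ml_equals_radius(self):
        fx = analytic_fixture("sphere_cap", radius=20.0, cap_angle_deg=60, n=60)
        res = measure_roc(fx.mesh, np.array([0.0, 0.0, 20.0]), self.SPHERE_CYL)
        assert res.ap_radius == pytest.approx(20.0, rel=0.02)
        assert res.ml_radius == pytest.approx(20.0, rel=0.02)

    def test_cylinder_convex_ap_and_flat_ml(self):
        fx = analytic_fixture("cylinder_patch", radius=20.0, height=60.0, arc_deg=150, n=60)
        cyl = fit_cylinder(fx.mesh.vertices)
        probe = np.array([20.0, 0.0, 0.0])
        res = measure_roc(fx.mesh, probe, cyl)
        assert res.ap_radius == pytest.approx(20.0, rel=0.02)
        assert res.ml_flat  # straight sections along the axis

    def test_saddle_signed_radii_exact(self):
        fx = analytic_fixture("saddle_patch", r_convex=25.6, r_concave=-15.7, n=60)
        t = fx.truth
        cyl = CylinderFit(axis_point=t["axis_point"], axis_direction=t["axis_direction"],
                          radius=25.6, rms_residual=0.0)
        res = measure_roc(fx.mesh, t["probe_point"], cyl, patch_area_mm2=100.0)
        assert res.ap_radius == pytest.approx(25.6, rel=0.01)
        assert res.ml_radius == pytest.approx(-15.7, rel=0.01)

    def test_condyle_truth_small_patch_limit(self):
        """Measured ML radii converge monotonically to the closed-form
        section curvature as the patch area shrinks, within 5% at 0.5 cm²;
        AP radii are exact (circular sections) at every size.  Signs follow
        the convex condyle / concave groove pattern."""
        cfg = CohortConfig(n_grid_u=96, n_grid_v=72)
        mesh = generate_base_surface(cfg)
        post, _ = select_posterior_articulating_surface(mesh)
        cyl = fit_cylinder(post.vertices)
        truth = probe_truth(cfg)
        for name, v in truth.items():
            prev_err = None
            for area in (400.0, 270.0, 100.0, 50.0):
                res = measure_roc(mesh, v["point"], cyl, patch_area_mm2=area)
                assert res.ap_radius == pytest.approx(v["ap_radius"], rel=0.02)
                assert np.sign(res.ml_radius) == np.sign(v["ml_radius"])
                err = abs(res.ml_radius - v["ml_radius"]) / abs(v["ml_radius"])
                if prev_err is not None:
                    assert err < prev_err
                prev_err = err
            assert prev_err < 0.05

    def test_rigid_invariance_of_radii(self):
        fx = analytic_fixture("saddle_patch", r_convex=25.6, r_concave=-15.7, n=50)
        t = fx.truth
        cyl = fit_cylinder(fx.mesh.vertices)
        res0 = measure_roc(fx.mesh, t["probe_point"], cyl, patch_area_mm2=100.0)
        R = Rotation.from_euler("xyz", [31, -47, 12], degrees=True).as_matrix()
        shift = np.array([12.0, -4.0, 9.0])
        moved = fx.mesh.transformed(rotation=R, translation=shift)
        cyl2 = fit_cylinder(moved.vertices)  # re-fit in the new pose
        probe2 = R @ t["probe_point"] + shift
        res1 = measure_roc(moved, probe2, cyl2, patch_area_mm2=100.0)
        assert res1.ap_radius == pytest.approx(res0.ap_radius, rel=1e-3)
        assert res1.ml_radius == pytest.approx(res0.ml_radius, rel=1e-3)


class TestProbePlacement:
    def test_equal_spacing_and_symmetry_about_apex(self):
        fx = analytic_fixture("cylinder_patch", radius=20.0, height=60.0, arc_deg=160, n=80)
        cyl = fit_cylinder(fx.mesh.vertices)
        apex = np.array([20.0, 0.0, 0.0])
        pts = place_probe_points(fx.mesh, apex, cyl, n=5, spacing=6.0)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        # chord lengths of equal arcs are equal
        assert np.allclose(gaps, gaps[0], atol=0.05)
        assert np.abs(pts[2] - apex).max() < 0.5  # middle point on the anchor
        # symmetric pairs about the apex
        assert np.allclose(pts[0][2], pts[4][2], atol=1e-6)
        assert np.abs(pts[0][1] + pts[4][1]).max() < 0.2

    def test_region_too_small_rejected(self):
        fx = analytic_fixture("cylinder_patch", radius=20.0, height=20.0, arc_deg=40, n=30)
        cyl = fit_cylinder(fx.mesh.vertices)
        with pytest.raises(ValueError):
            place_probe_points(fx.mesh, np.array([20.0, 0.0, 0.0]), cyl, n=5, spacing=25.0)


class TestPosteriorSelection:
    def test_label_passthrough_and_strict_subset(self, base_surface):
        sub, mask = select_posterior_articulating_surface(base_surface)
        labels = base_surface.face_labels[mask]
        assert set(labels) <= {"medial_condyle", "lateral_condyle"}
        from cartmorph import surface_area

        assert surface_area(sub) < surface_area(base_surface)

    def test_plane_fully_posterior_empty_selection(self, base_surface):
        with pytest.raises(ValueError):
            select_posterior_articulating_surface(
                base_surface, plane_point=(0.0, -1000.0, 0.0)
            )
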