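"""GPA alignment and the PCA shape model."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cartmorph import (
    CohortConfig,
    GeneralizedProcrustes,
    StatisticalShapeModel,
    ap_ml_dimensions,
    evaluate_ssm,
    generate_base_surface,
    generate_cohort,
    similarity_procrustes,
)
from cartmorph.synthetic import radial_profile, surface_point


def _planted_shapes(seed=11, k=70, amps=(2.0, 1.0)):
    cfg = CohortConfig(
        n_models=k, n_grid_u=24, n_grid_v=18, mode_amplitudes=amps,
        vertex_noise_sd=0.0, side_mix=0.0, seed=seed,
    )
    cohort = generate_cohort(cfg)
    return np.stack([m.vertices for m in cohort.native_meshes]), cohort


class TestGPA:
    def test_rotated_copy_aligns_exactly(self, base_surface):
        R = Rotation.from_euler("x", 45, degrees=True).as_matrix()
        shapes = np.stack([base_surface.vertices, base_surface.vertices @ R.T])
        est = GeneralizedProcrustes().fit(shapes)
        assert np.abs(est.aligned_[0] - est.aligned_[1]).max() < 1e-9

    def test_no_scaling_preserves_centroid_sizes(self):
        shapes, _ = _planted_shapes(seed=5, k=6)
        est = GeneralizedProcrustes(with_scaling=False).fit(shapes)
        before = np.sqrt(((shapes - shapes.mean(1, keepdims=True)) ** 2).sum((1, 2)))
        after = np.sqrt((est.aligned_**2).sum((1, 2)))
        np.testing.assert_allclose(after, before, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_invariant_to_rigid_perturbations(self, seed):
        """Rigidly scrambling the cohort leaves the GPA mean unchanged (up
        to the global orientation gauge) to 1e-4 mm."""
        shapes, _ = _planted_shapes(seed=31, k=8)
        rng = np.random.default_rng(seed)
        perturbed = np.stack([
            s @ Rotation.random(random_state=int(rng.integers(2**31))).as_matrix().T
            + rng.normal(0, 10, 3)
            for s in shapes
        ])
        m1 = GeneralizedProcrustes().fit(shapes).mean_
        m2 = GeneralizedProcrustes().fit(perturbed).mean_
        _, R, t = similarity_procrustes(m2, m1, with_scaling=False)
        assert np.abs(m2 @ R.T + t - m1).max() < 1e-4


class TestSSM:
    def test_identical_shapes_give_zero_modes(self, base_surface):
        shapes = np.stack([base_surface.vertices] * 10)
        model = StatisticalShapeModel().fit(shapes)
        assert model.n_modes_ == 0
        np.testing.assert_allclose(model.mean_.reshape(-1, 3), base_surface.vertices)

    def test_planted_two_mode_structure_recovered(self):
        shapes, cohort = _planted_shapes(seed=11, k=70, amps=(2.0, 1.0))
        aligned = GeneralizedProcrustes().fit(shapes).aligned_
        model = StatisticalShapeModel().fit(aligned)
        assert model.n_modes_ == 2  # exactly two non-negligible modes
        ratio = np.sqrt(model.explained_variance_[0] / model.explained_variance_[1])
        assert ratio == pytest.approx(2.0, rel=0.35)  # within k=70 sampling error

    def test_planted_mode_subspace_recovered(self):
        """The recovered leading modes span the planted fields once mapped
        back into the generator frame (the GPA result carries a global
        orientation gauge), and the residual angle shrinks with the planted
        amplitude."""
        angles = []
        for f in (1.0, 0.25):
            shapes, cohort = _planted_shapes(seed=13, k=40, amps=(2.0 * f, 1.0 * f))
            aligned = GeneralizedProcrustes().fit(shapes).aligned_
            model = StatisticalShapeModel().fit(aligned)
            # undo the alignment gauge: rotate modes into the base frame
            _, R, _ = similarity_procrustes(
                model.mean_.reshape(-1, 3), cohort.base.vertices, with_scaling=False
            )
            P = (model.components_.reshape(2, -1, 3) @ R.T).reshape(2, -1).T
            Q = cohort.mode_basis
            sv = np.linalg.svd(Q.T @ P, compute_uv=False)
            angles.append(np.degrees(np.arccos(np.clip(sv, -1, 1))).max())
        assert angles[0] < 2.0
        assert angles[1] < angles[0]

    def test_training_shapes_reconstructed_exactly_with_all_modes(self):
        shapes, _ = _planted_shapes(seed=17, k=6)
        aligned = GeneralizedProcrustes().fit(shapes).aligned_
        model = StatisticalShapeModel().fit(aligned)
        rec = model.inverse_transform(model.transform(aligned))
        assert np.abs(rec - aligned).max() < 1e-6

    def test_synthesis_is_linear_and_symmetric(self):
        shapes, _ = _planted_shapes(seed=19, k=6)
        model = StatisticalShapeModel().fit(GeneralizedProcrustes().fit(shapes).aligned_)
        mean = model.mean_.reshape(-1, 3)
        b = np.zeros(model.n_modes_)
        np.testing.assert_allclose(model.inverse_transform(b)[0], mean)
        b[0] = 1.7
        plus = model.inverse_transform(b)[0]
        minus = model.inverse_transform(-b)[0]
        np.testing.assert_allclose(mean - minus, plus - mean, atol=1e-10)

    def test_projection_synthesis_round_trip(self):
        shapes, _ = _planted_shapes(seed=23, k=10)
        model = StatisticalShapeModel().fit(GeneralizedProcrustes().fit(shapes).aligned_)
        rng = np.random.default_rng(0)
        b = rng.uniform(-3, 3, (20, model.n_modes_)) * np.sqrt(model.explained_variance_)
        b_back = model.transform(model.inverse_transform(b))
        assert np.abs(b_back - b).max() < 1e-8

    def test_total_variance_conserved(self):
        shapes, _ = _planted_shapes(seed=29, k=12)
        aligned = GeneralizedProcrustes().fit(shapes).aligned_
        model = StatisticalShapeModel().fit(aligned)
        flat = aligned.reshape(len(aligned), -1)
        total = ((flat - flat.mean(0)) ** 2).sum() / (len(flat) - 1)
        assert model.explained_variance_.sum() == pytest.approx(total, rel=1e-6)

    def test_b_longer_than_modes_rejected(self):
        shapes, _ = _planted_shapes(seed=3, k=5)
        model = StatisticalShapeModel().fit(GeneralizedProcrustes().fit(shapes).aligned_)
        with pytest.raises(ValueError):
            model.inverse_transform(np.zeros(model.n_modes_ + 1))


@pytest.fixture(scope="module")
def model():
    shapes, _ = _planted_shapes(seed=37, k=70, amps=(2.0, 1.0, 0.5))
    return StatisticalShapeModel().fit(GeneralizedProcrustes().fit(shapes).aligned_)


class TestSampling:
    def test_zero_truncation_collapses_to_mean(self, model):
        b = model.sample_coefficients(10, random_state=1, truncation_sd=0.0)
        assert np.abs(b).max() == 0.0

    def test_coefficient_means_near_zero(self, model):
        b = model.sample_coefficients(200, random_state=2)
        se = np.sqrt(model.explained_variance_ / 200)
        assert np.all(np.abs(b.mean(axis=0)) < 3 * se)

    def test_per_mode_variance_matches_lambda(self, model):
        b = model.sample_coefficients(200, random_state=3)
        var = b.var(axis=0, ddof=1)
        for j in range(min(3, model.n_modes_)):
            assert var[j] == pytest.approx(model.explained_variance_[j], rel=0.25)

    def test_sampling_deterministic_under_seed(self, model):
        a = model.sample_coefficients(5, random_state=9)
        b = model.sample_coefficients(5, random_state=9)
        np.testing.assert_array_equal(a, b)


class TestEvaluation:
    def test_curves_contracts(self):
        shapes, _ = _planted_shapes(seed=41, k=8)
        aligned = GeneralizedProcrustes().fit(shapes).aligned_
        ev = evaluate_ssm(aligned)
        assert ev.compactness[-1] == pytest.approx(1.0)
        assert np.all(np.diff(ev.compactness) >= -1e-12)
        assert np.all(np.diff(ev.accuracy_rms) <= 1e-9)  # nested projections
        assert np.all(ev.accuracy_rms >= 0)
        assert ev.generalisation_rms is not None
        assert np.all(ev.generalisation_rms >= ev.accuracy_rms[: len(ev.generalisation_rms)] - 1e-12)

    def test_planted_cohort_compact_at_two_modes(self):
        shapes, _ = _planted_shapes(seed=43, k=30)
        ev = evaluate_ssm(GeneralizedProcrustes().fit(shapes).aligned_)
        assert ev.compactness[1] >= 0.99


class TestApMl:
    def test_dimensions_match_dense_closed_form(self, tiny_config):
        mesh = generate_base_surface(tiny_config)
        ap, ml = ap_ml_dimensions(mesh)
        # oracle: evaluate the parametric surface on a dense grid
        cfg = tiny_config
        xs = np.linspace(-cfg.ml_extent / 2, cfg.ml_extent / 2, 600)
        half = cfg.ap_extent / cfg.condyle_radius / 2
        ts = np.linspace(cfg.theta_offset - half, cfg.theta_offset + half, 600)
        X, T = np.meshgrid(xs, ts, indexing="ij")
        P = surface_point(cfg, X.ravel(), T.ravel())
        ml_truth = cfg.ml_extent
        quarter = cfg.condyle_separation / 4
        med = P[X.ravel() > quarter]
        lat = P[X.ravel() < -quarter]
        pm = med[np.argmin(med[:, 1])]
        pl = lat[np.argmin(lat[:, 1])]
        ant = P[np.argmax(P[:, 1])]
        d = pl - pm
        ap_truth = np.linalg.norm(np.cross(ant - pm, d)) / np.linalg.norm(d)
        tol = mesh.mean_edge_length()
        assert ml == pytest.approx(ml_truth, abs=tol)
        assert ap == pytest.approx(ap_truth, abs=tol)

    def test_invariant_after_realignment(self, base_surface):
        ap0, ml0 = ap_ml_dimensions(base_surface)
        R = Rotation.from_euler("zy", [20, -10], degrees=True).as_matrix()
        moved = base_surface.transformed(rotation=R, translation=[4, 5, 6])
        # re-align to the working frame, then re-measure
        _, Rb, tb = similarity_procrustes(moved.vertices, base_surface.vertices,
                                          with_scaling=False)
        back = moved.transformed(rotation=Rb, translation=tb)
        ap1, ml1 = ap_ml_dimensions(back)
        assert ap1 == pytest.approx(ap0, abs=1e-3)
        assert ml1 == pytest.approx(ml0, abs=1e-3)

    def test_missing_labels_rejected(self, base_surface):
        bare = base_surface.copy()
        bare.face_labels = None
        with pytest.raises(ValueError):
            ap_ml_dimensions(bare)
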