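"""Procrustes alignment (no scaling, no reflection) and the PCA shape model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cavishape.model import (
    CorrespondedPopulation,
    PointDistributionModel,
    ProcrustesAligner,
    build_model,
    matrix_to_points,
    procrustes_align,
    project,
    quaternion_rotation,
    shapes_to_matrix,
    synthesize,
)


def random_shape(rng, n=80, scale=10.0):
    return rng.normal(0, scale, (n, 3))


def rigidly_moved(pts, rng):
    r = Rotation.random(random_state=int(rng.integers(2**16))).as_matrix()
    return pts @ r.T + rng.normal(0, 20, 3)


def plant_modes(rng, n_s, n_pts=120, sds=(3.0, 1.5, 0.7)):
    """Population = mean + sum c_i q_i with q_i orthonormal and orthogonal
    to the rigid-motion generators at the mean (so Procrustes is neutral)."""
    mean = random_shape(rng, n_pts)
    mean -= mean.mean(axis=0)
    gens = []
    for k in range(3):
        t = np.zeros((n_pts, 3))
        t[:, k] = 1.0
        gens.append(shapes_to_matrix(t[None])[0])
    for axis in np.eye(3):
        gens.append(shapes_to_matrix(np.cross(axis, mean)[None])[0])
    basis = []
    for _ in range(len(sds)):
        q = rng.normal(size=3 * n_pts)
        for p in gens + basis:
            q -= (q @ p) / (p @ p) * p
        basis.append(q / np.linalg.norm(q))
    coeffs = rng.normal(0, sds, size=(n_s, len(sds)))
    x = shapes_to_matrix(np.tile(mean, (n_s, 1, 1))) + coeffs @ np.array(basis)
    return x, np.array(basis), coeffs


class TestQuaternionRotation:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        a = random_shape(rng)
        r_true = Rotation.from_euler("zyx", [0.5, -0.2, 1.0]).as_matrix()
        r = quaternion_rotation(a, a @ r_true.T)
        np.testing.assert_allclose(r, r_true, atol=1e-12)

    def test_never_a_reflection(self):
        rng = np.random.default_rng(1)
        a = random_shape(rng)
        mirrored = a * np.array([1.0, -1.0, 1.0])
        r = quaternion_rotation(a, mirrored)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


class TestProcrustes:
    def test_rotated_translated_copy_recovered_exactly(self):
        rng = np.random.default_rng(2)
        base = random_shape(rng)
        moved = rigidly_moved(base, rng)
        x = shapes_to_matrix(np.stack([base, moved]))
        aligned = ProcrustesAligner().fit_transform(x)
        pts = matrix_to_points(aligned)
        rmsd = np.sqrt(np.mean((pts[0] - pts[1]) ** 2))
        assert rmsd < 1e-9

    def test_scale_is_preserved(self):
        rng = np.random.default_rng(3)
        base = random_shape(rng)
        x = shapes_to_matrix(np.stack([base, base * 2.0]))
        aligned = matrix_to_points(ProcrustesAligner().fit_transform(x))
        norm0 = np.linalg.norm(aligned[0] - aligned[0].mean(0))
        norm1 = np.linalg.norm(aligned[1] - aligned[1].mean(0))
        assert norm1 / norm0 == pytest.approx(2.0, rel=1e-9)

    def test_reflection_not_used_for_mirrored_shape(self):
        rng = np.random.default_rng(4)
        base = random_shape(rng)
        mirrored = base * np.array([1.0, -1.0, 1.0])
        aligned = matrix_to_points(
            ProcrustesAligner().fit_transform(
                shapes_to_matrix(np.stack([base, mirrored]))
            )
        )
        # a proper rotation cannot undo a reflection of a chiral shape
        assert np.abs(aligned[0] - aligned[1]).max() > 1.0

    def test_equivariance_under_random_rotations(self):
        rng = np.random.default_rng(5)
        shapes = np.stack([random_shape(rng) for _ in range(6)])
        x = shapes_to_matrix(shapes)
        a1 = matrix_to_points(ProcrustesAligner().fit_transform(x))
        moved = np.stack([rigidly_moved(s, rng) for s in shapes])
        a2 = matrix_to_points(
            ProcrustesAligner().fit_transform(shapes_to_matrix(moved))
        )
        # the two aligned sets agree up to one global rotation
        r = quaternion_rotation(
            a2.reshape(-1, 3), a1.reshape(-1, 3)
        )
        np.testing.assert_allclose(a2 @ r.T, a1, atol=1e-6)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(6)
        shapes = np.stack(
            [rigidly_moved(random_shape(rng), rng) for _ in range(5)]
        )
        aligner = ProcrustesAligner(max_iter=1).fit(shapes_to_matrix(shapes))
        one = matrix_to_points(aligner.aligned_)
        full = matrix_to_points(
            ProcrustesAligner(max_iter=20).fit(shapes_to_matrix(shapes)).aligned_
        )

        def spread(pts):
            return ((pts - pts.mean(axis=0)) ** 2).sum()

        assert spread(full) <= spread(one) + 1e-9

    def test_degenerate_shape_rejected(self):
        x = np.zeros((2, 9))
        with pytest.raises(ValueError, match="degenerate"):
            ProcrustesAligner().fit(x)


class TestPointDistributionModel:
    def test_two_point_population_single_mode(self):
        rng = np.random.default_rng(7)
        mean = rng.normal(size=60)
        d = rng.normal(size=60)
        model = PointDistributionModel().fit(np.vstack([mean + d, mean - d]))
        assert model.n_modes_ == 1
        cos = abs(model.components_[0] @ d / np.linalg.norm(d))
        assert cos == pytest.approx(1.0, rel=1e-9)

    def test_mirror_closed_population_symmetric_mean(self):
        rng = np.random.default_rng(8)
        pts = np.stack([random_shape(rng, 50) for _ in range(6)])
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        both = np.concatenate([pts, mirrored])
        model = PointDistributionModel().fit(shapes_to_matrix(both))
        mean_pts = matrix_to_points(model.mean_)
        np.testing.assert_allclose(
            mean_pts, mean_pts * np.array([1.0, -1.0, 1.0]), atol=1e-6
        )

    def test_planted_three_mode_recovery(self):
        rng = np.random.default_rng(9)
        x, basis, coeffs = plant_modes(rng, n_s=40)
        aligned = ProcrustesAligner().fit_transform(x)
        model = PointDistributionModel().fit(aligned)
        lam = model.variances_
        assert lam[:3].sum() / lam.sum() >= 0.95
        emp = coeffs.var(axis=0, ddof=1)
        for i in range(3):
            assert lam[i] == pytest.approx(np.sort(emp)[::-1][i], rel=0.25)
        # subspace angle between planted and recovered spans
        from scipy.linalg import subspace_angles

        ang = subspace_angles(basis.T, model.components_[:3].T)
        assert np.degrees(ang.max()) < 5.0

    def test_variance_conservation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 90))
        model = PointDistributionModel().fit(x)
        xc = x - x.mean(axis=0)
        total = (xc**2).sum() / (len(x) - 1)
        assert model.variances_.sum() == pytest.approx(total, rel=1e-8)

    def test_orthonormal_modes(self):
        rng = np.random.default_rng(11)
        model = PointDistributionModel().fit(rng.normal(size=(8, 45)))
        gram = model.components_ @ model.components_.T
        np.testing.assert_allclose(gram, np.eye(model.n_modes_), atol=1e-8)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(12)
    x, _, _ = plant_modes(rng, n_s=15)
    return PointDistributionModel().fit(ProcrustesAligner().fit_transform(x))


class TestSynthesisProjection:
    def test_zero_coefficients_give_mean(self, fitted):
        x = synthesize(fitted, np.zeros(fitted.n_modes_))
        np.testing.assert_array_equal(x, fitted.mean_)

    def test_clamping_at_three_sd(self, fitted):
        sd1 = np.sqrt(fitted.variances_[0])
        x_over = synthesize(fitted, [3.5 * sd1])
        x_at = synthesize(fitted, [3.0 * sd1])
        np.testing.assert_allclose(x_over, x_at, atol=1e-12)
        _, clamped = fitted.synthesize([3.5 * sd1])
        assert clamped == [0]

    def test_projection_roundtrip_on_training_shape(self, fitted):
        rng = np.random.default_rng(13)
        b = rng.normal(0, np.sqrt(fitted.variances_))
        x = synthesize(fitted, b, clamp=False)
        b_back = project(fitted, x)
        x_back = synthesize(fitted, b_back, clamp=False)
        np.testing.assert_allclose(x_back, x, atol=1e-8)

    def test_projection_of_mean_is_zero(self, fitted):
        assert np.abs(project(fitted, fitted.mean_)).max() < 1e-10

    def test_single_mode_displacement_projects_exactly(self, fitted):
        sd2 = np.sqrt(fitted.variances_[1])
        x = fitted.mean_ + 2 * sd2 * fitted.components_[1]
        b = project(fitted, x)
        assert b[1] == pytest.approx(2 * sd2, rel=1e-9)
        others = np.delete(b, 1)
        assert np.abs(others).max() < 1e-9 * sd2

    def test_training_projection_variance_matches_spectrum(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(10, 60))
        model = PointDistributionModel().fit(x)
        b = model.transform(x)
        np.testing.assert_allclose(
            b.var(axis=0, ddof=1), model.variances_, rtol=1e-6
        )


class TestCompactness:
    def test_hand_case(self):
        model = PointDistributionModel()
        model.variances_ = np.array([3.0, 1.0])
        curve, m = model.compactness(0.75)
        np.testing.assert_allclose(curve, [0.75, 1.0])
        assert m == 1

    def test_full_threshold_needs_all_modes(self):
        model = PointDistributionModel()
        model.variances_ = np.array([3.0, 1.0, 0.5])
        _, m = model.compactness(1.0)
        assert m == 3

    def test_zero_spectrum_rejected(self):
        model = PointDistributionModel()
        model.variances_ = np.zeros(3)
        with pytest.raises(ValueError):
            model.compactness()


class TestContainersAndWrappers:
    def test_population_hdf5_roundtrip(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(15)
        pop = CorrespondedPopulation(
            rng.normal(size=(4, 30, 3)),
            pd.DataFrame({"subject_id": range(4), "age": [20, 30, 40, 50.0],
                          "sex": list("FMFM")}),
            grid=(5, 6),
        )
        path = tmp_path / "pop.h5"
        pop.to_hdf5(path)
        back = CorrespondedPopulation.from_hdf5(path)
        np.testing.assert_array_equal(back.landmarks, pop.landmarks)
        assert back.grid == (5, 6)
        assert list(back.covariates["sex"]) == list("FMFM")

    def test_model_hdf5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(16)
        model = PointDistributionModel().fit(rng.normal(size=(6, 36)))
        path = tmp_path / "model.h5"
        model.to_hdf5(path)
        back = PointDistributionModel.from_hdf5(path)
        np.testing.assert_array_equal(back.mean_, model.mean_)
        np.testing.assert_array_equal(back.components_, model.components_)
        np.testing.assert_array_equal(back.variances_, model.variances_)

    def test_functional_wrappers_match_estimators(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(5, 20, 3))
        pop = CorrespondedPopulation(pts)
        aligned = procrustes_align(pop)
        model = build_model(aligned)
        direct = PointDistributionModel().fit(
            ProcrustesAligner().fit_transform(shapes_to_matrix(pts))
        )
        np.testing.assert_allclose(model.mean_, direct.mean_, atol=1e-12)

    def test_population_ply_export_shares_vertex_order(self, tmp_path):
        from cavishape.geometry import read_mesh

        rng = np.random.default_rng(18)
        pop = CorrespondedPopulation(rng.normal(size=(3, 20, 3)), grid=(4, 5))
        pop.to_ply_dir(tmp_path)
        meshes = [read_mesh(p) for p in sorted(tmp_path.glob("*.ply"))]
        assert len(meshes) == 3
        for m in meshes:
            assert m.n_vertices == 20
            np.testing.assert_array_equal(m.faces, meshes[0].faces)

    def test_sklearn_get_set_params(self):
        model = PointDistributionModel(clamp=False, clamp_sd=2.5)
        params = model.get_params()
        assert params["clamp"] is False
        model.set_params(clamp_sd=3.0)
        assert model.clamp_sd == 3.0
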