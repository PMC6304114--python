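"""Region partitioning, capping, and volume/area/SVR sweeps."""

import numpy as np
import pytest

from cavishape.geometry import Surface, enclosed_volume
from cavishape.model import PointDistributionModel, shapes_to_matrix
from cavishape.morphometrics import (
    close_region,
    cv_table,
    define_regions,
    grid_surface,
    morpho_table,
    region_measures,
    variation_coefficient,
)


N_U, N_V = 24, 31  # rows at z = 40 j / 30: clean cuts at z = 20 and thirds
RADIUS, HEIGHT = 10.0, 40.0


def tube_landmarks():
    alpha = 2 * np.pi * np.arange(N_U) / N_U
    z = np.linspace(0, HEIGHT, N_V)
    return np.array(
        [
            [RADIUS * np.cos(a), RADIUS * np.sin(a), zz]
            for a in alpha
            for zz in z
        ]
    )


BOXES = {
    "NVVR": ((-12, -12, -1), (12, 12, 12)),
    "OR": ((-12, -12, 13), (12, 12, 25)),
    "PNR": ((-12, -12, 26), (12, 12, 41)),
}


@pytest.fixture(scope="module")
def tube_surface():
    return grid_surface(tube_landmarks(), N_U, N_V)


@pytest.fixture(scope="module")
def partition(tube_surface):
    return define_regions(tube_surface, BOXES)


def model_with_mode(field, variance=25.0):
    pts = tube_landmarks()
    model = PointDistributionModel()
    model.mean_ = shapes_to_matrix(pts[None])[0]
    fvec = shapes_to_matrix(field[None])[0]
    model.components_ = (fvec / np.linalg.norm(fvec))[None]
    model.variances_ = np.array([variance])
    model.n_shapes_ = 10
    model.n_features_in_ = len(model.mean_)
    return model


class TestDefineRegions:
    def test_empty_boxes_give_all_rr(self, tube_surface):
        part = define_regions(tube_surface, {})
        assert set(part.face_labels) == {"RR"}

    def test_brute_force_centroid_oracle(self, tube_surface, partition):
        lo = np.array(BOXES["OR"][0], float)
        hi = np.array(BOXES["OR"][1], float)
        expected = set()
        for fi, tri in enumerate(tube_surface.faces):  # independent scan
            c = tube_surface.vertices[tri].mean(axis=0)
            if np.all(c >= lo) and np.all(c <= hi):
                expected.add(fi)
        assert set(partition.faces_of("OR").tolist()) == expected

    def test_every_face_labelled_once(self, tube_surface, partition):
        assert len(partition.face_labels) == tube_surface.n_faces
        counts = sum(
            len(partition.faces_of(r)) for r in ("NVVR", "OR", "PNR", "RR")
        )
        assert counts == tube_surface.n_faces

    def test_overlapping_boxes_rejected(self, tube_surface):
        bad = dict(BOXES)
        bad["OR"] = ((-12, -12, 5), (12, 12, 25))
        with pytest.raises(ValueError, match="overlap"):
            define_regions(tube_surface, bad)

    def test_labels_transfer_by_index(self, tube_surface, partition):
        # deform the grid: labels follow triangle indices unchanged
        pts2 = tube_landmarks() * 1.3
        surf2 = grid_surface(pts2, N_U, N_V)
        assert surf2.n_faces == tube_surface.n_faces
        # same index sets select corresponding triangles on the new shape
        sel = partition.faces_of("NVVR")
        np.testing.assert_array_equal(
            surf2.faces[sel], tube_surface.faces[sel]
        )


class TestCloseRegion:
    def test_half_cylinder_volume(self, tube_surface, partition):
        # faces with centroid below z = 20 are exactly half the tube; the
        # capped half must hold half the capped full-tube volume, and both
        # must sit within 2% of the analytic pi r^2 h (chord-polygon gap)
        centroids = tube_surface.vertices[tube_surface.faces].mean(axis=1)
        half = np.flatnonzero(centroids[:, 2] < HEIGHT / 2)
        closed = close_region(tube_surface, half)
        full = close_region(tube_surface, np.arange(tube_surface.n_faces))
        assert enclosed_volume(closed) == pytest.approx(
            enclosed_volume(full) / 2, rel=1e-9
        )
        analytic = np.pi * RADIUS**2 * (HEIGHT / 2) / 1000.0
        assert enclosed_volume(closed) == pytest.approx(analytic, rel=0.02)

    def test_closed_region_unchanged(self):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        surf = Surface(np.asarray(ico.vertices), np.asarray(ico.faces))
        out = close_region(surf, np.arange(surf.n_faces))
        assert out.n_faces == surf.n_faces
        assert out.is_watertight()

    def test_tube_segment_gets_both_caps(self, tube_surface):
        # middle third of the rows: two boundary loops, both capped
        z_lo, z_hi = HEIGHT / 3, 2 * HEIGHT / 3
        centroids = tube_surface.vertices[tube_surface.faces].mean(axis=1)
        band = np.flatnonzero(
            (centroids[:, 2] > z_lo) & (centroids[:, 2] < z_hi)
        )
        closed = close_region(tube_surface, band)
        assert closed.is_watertight()
        full = close_region(tube_surface, np.arange(tube_surface.n_faces))
        assert enclosed_volume(closed) == pytest.approx(
            enclosed_volume(full) / 3, rel=1e-9
        )

    def test_planar_bowtie_loop_rejected(self):
        # flat ribbon whose single boundary is a figure-eight in its plane
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        outer = np.column_stack(
            [np.sin(2 * t) * 10, np.sin(t) * 10, 0 * t]
        )  # lemniscate: self-crossing
        centre = np.array([[0.0, 0.0, 0.0]])
        verts = np.vstack([centre, outer])
        faces = np.array(
            [[0, 1 + i, 1 + (i + 1) % 40] for i in range(40)]
        )
        # remove two fan triangles so the lemniscate becomes boundary of an
        # open (disc-like) patch
        surf = Surface(verts, faces)
        with pytest.raises(ValueError, match="self-intersect"):
            close_region(surf, np.arange(0, 39))


class TestRegionMeasures:
    def test_k_zero_row_equals_mean_measures(self, partition):
        field = np.zeros((N_U * N_V, 3))
        field[:, 2] = np.linspace(0, 1, N_U * N_V)
        model = model_with_mode(field)
        df = region_measures(model, partition, 0, (N_U, N_V))
        row = df[(df.k == 0.0) & (df.region == "total")].iloc[0]
        mean_surf = grid_surface(tube_landmarks(), N_U, N_V)
        closed = close_region(mean_surf, np.arange(mean_surf.n_faces))
        assert row.volume_cm3 == pytest.approx(enclosed_volume(closed),
                                               rel=1e-9)

    def test_volume_additivity_exact(self, partition):
        pts = tube_landmarks()
        field = (pts - pts.mean(axis=0))
        model = model_with_mode(field)
        df = region_measures(model, partition, 0, (N_U, N_V))
        total = df[df.region == "total"].sort_values("k").volume_cm3.to_numpy()
        parts = (
            df[df.region != "total"].groupby("k").volume_cm3.sum().to_numpy()
        )
        np.testing.assert_allclose(parts, total, rtol=1e-12)

    def test_scaling_mode_power_laws(self, partition):
        pts = tube_landmarks()
        field = pts - pts.mean(axis=0)
        nrm = np.linalg.norm(shapes_to_matrix(field[None])[0])
        model = model_with_mode(field)
        df = region_measures(model, partition, 0, (N_U, N_V))
        tot = df[df.region == "total"].set_index("k")
        v0, a0 = tot.loc[0.0, "volume_cm3"], tot.loc[0.0, "area_cm2"]
        for k in (-2.5, -1.25, 1.25, 2.5):
            s = 1 + k * 5.0 / nrm
            assert tot.loc[k, "volume_cm3"] / v0 == pytest.approx(s**3,
                                                                  rel=0.01)
            assert tot.loc[k, "area_cm2"] / a0 == pytest.approx(s**2,
                                                                rel=0.01)
            svr = tot.loc[k, "area_cm2"] / tot.loc[k, "volume_cm3"]
            assert svr / (a0 / v0) == pytest.approx(1 / s, rel=0.01)

    def test_antisymmetric_mode_mirror_equal_measures(self, partition):
        z = np.linspace(0, HEIGHT, N_V)
        w = np.sin(np.pi * np.tile(z / HEIGHT, N_U))
        field = np.zeros((N_U * N_V, 3))
        field[:, 1] = w
        model = model_with_mode(field)
        df = region_measures(model, partition, 0, (N_U, N_V))
        for region in ("NVVR", "OR", "PNR", "RR"):
            sub = df[df.region == region].set_index("k")
            for k in (1.25, 2.5):
                assert sub.loc[k, "volume_cm3"] == pytest.approx(
                    sub.loc[-k, "volume_cm3"], rel=1e-3
                )
                assert sub.loc[k, "area_cm2"] == pytest.approx(
                    sub.loc[-k, "area_cm2"], rel=1e-3
                )
        cvs = cv_table(df)
        assert cvs.cv.abs().max() < 0.01


class TestVariationCoefficient:
    def test_constant_values_zero(self):
        assert variation_coefficient([2.0] * 5) == 0.0

    def test_hand_case(self):
        assert variation_coefficient([1, 2, 3, 4, 5]) == pytest.approx(
            1.5811388300841898 / 3.0
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 2, 5)
        assert variation_coefficient(7.3 * v) == pytest.approx(
            variation_coefficient(v), rel=1e-12
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            variation_coefficient([-1.0, 1.0])


def test_morpho_table_covers_modes(partition):
    pts = tube_landmarks()
    field = pts - pts.mean(axis=0)
    model = model_with_mode(field)
    table = morpho_table(model, partition, (N_U, N_V))
    assert set(table["mode"]) == {0}
    assert set(table[table.region != "total"].region) == {
        "NVVR", "OR", "PNR", "RR",
    }
    cvs = cv_table(table)
    assert len(cvs) == 4 * 3
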