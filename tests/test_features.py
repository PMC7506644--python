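"""Geometry primitives, the feature catalog and extraction invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import geomexpr as gx
from geomexpr.catalog import builtin_catalog, ga_selected_catalog, ga_selected_mask

finite_coord = st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False)
point3 = st.tuples(finite_coord, finite_coord, finite_coord)


class TestDistance:
    def test_3_4_5_triangle(self):
        assert gx.euclidean_distance((0, 0, 0), (3, 4, 0)) == 5.0

    def test_identity(self):
        assert gx.euclidean_distance((1.5, -2, 7), (1.5, -2, 7)) == 0.0

    def test_matches_sum_of_squares_oracle(self, rng):
        pts = rng.normal(scale=100, size=(1000, 2, 3))
        for p, q in pts:
            oracle = sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5
            assert gx.euclidean_distance(p, q) == pytest.approx(oracle, abs=1e-9)


class TestAngle:
    def test_orthogonal_arms(self):
        assert gx.angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(np.pi / 2)

    def test_collinear_opposite(self):
        assert gx.angle((1, 0, 0), (0, 0, 0), (-1, 0, 0)) == pytest.approx(np.pi)

    def test_law_of_cosines_oracle(self, rng):
        """arccos((a^2+b^2-c^2)/2ab) on the triangle side lengths."""
        for _ in range(1000):
            p1, p2, p3 = rng.normal(scale=50, size=(3, 3))
            a = np.linalg.norm(p1 - p2)
            b = np.linalg.norm(p3 - p2)
            c = np.linalg.norm(p3 - p1)
            oracle = np.arccos(np.clip((a**2 + b**2 - c**2) / (2 * a * b), -1, 1))
            assert gx.angle(p1, p2, p3) == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_arm_identified(self):
        with pytest.raises(ValueError, match="p1"):
            gx.angle((0, 0, 0), (0, 0, 0), (1, 0, 0))
        with pytest.raises(ValueError, match="p3"):
            gx.angle((1, 0, 0), (0, 0, 0), (0, 0, 0))

    @given(p=point3, scale=st.floats(1e-3, 1e3))
    def test_never_nan_on_near_collinear(self, p, scale):
        """Clamping keeps arccos defined when round-off pushes |cos|>1."""
        p = np.asarray(p)
        if np.linalg.norm(p) < 1e-6:
            p = p + 1.0
        v = gx.angle(p * scale, (0.0, 0.0, 0.0), p * 7.0)
        assert np.isfinite(v) and 0 <= v <= np.pi
        v = gx.angle(p * scale, (0.0, 0.0, 0.0), -p * 3.0)
        assert np.isfinite(v) and 0 <= v <= np.pi


class TestNormalizer:
    def test_self_normalization(self, template):
        d89 = gx.euclidean_distance(template[8].xyz, template[9].xyz)
        assert d89 / gx.normalizer(template) == pytest.approx(1.0)

    def test_scale_cancellation(self, template):
        scaled = template.transformed(lambda a: 3.0 * a)
        v0 = gx.extract_features(template).values
        v1 = gx.extract_features(scaled).values
        assert np.allclose(v0, v1, atol=1e-9)

    def test_translation_invariance(self, template):
        moved = template.transformed(lambda a: a + np.array([10.0, -20.0, 5.0]))
        assert gx.normalizer(moved) == pytest.approx(gx.normalizer(template), abs=1e-9)


class TestCatalog:
    def test_builtin_counts(self):
        cat = builtin_catalog()
        assert len(cat) == 89
        counts = cat.group_counts()
        assert counts == {
            "3D_angle": 27,
            "3D_distance": 19,
            "2D_angle": 20,
            "2D_distance": 23,
        }

    def test_ga_selected_counts(self):
        sel = ga_selected_catalog()
        assert len(sel) == 47
        assert sel.group_counts() == {
            "3D_angle": 14,
            "3D_distance": 12,
            "2D_angle": 8,
            "2D_distance": 13,
        }

    def test_selected_ids_subset_of_catalog(self):
        assert set(gx.ga_selected_ids()) <= set(builtin_catalog().ids)
        assert int(ga_selected_mask().sum()) == 47

    def test_angle_vertices_are_middle_element(self):
        for d in builtin_catalog():
            if d.kind == "angle":
                assert len(d.landmarks) == 3
            else:
                assert len(d.landmarks) == 2

    def test_catalog_order_fixed(self):
        ids = builtin_catalog().ids
        assert ids[0] == "1D3" and ids[18] == "19D3"
        assert ids[19] == "1A3" and ids[45] == "27A3"
        assert ids[46] == "1D2" and ids[68] == "23D2"
        assert ids[69] == "1A2" and ids[88] == "20A2"


def similarity(rng, coords, out_of_plane=True):
    from conftest import random_rotation

    if out_of_plane:
        R = random_rotation(rng)
    else:
        th = rng.uniform(0, 2 * np.pi)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
    s = rng.uniform(0.5, 2.0)
    t = rng.normal(scale=30, size=3)
    if not out_of_plane:
        t = t * np.array([1.0, 1.0, 0.0])
    return s * coords @ R.T + t


class TestExtraction:
    def test_vector_length_89(self, template):
        assert len(gx.extract_features(template).values) == 89

    def test_3d_features_similarity_invariant(self, template, rng):
        cat = builtin_catalog()
        idx3 = np.array([d.space == "3D" for d in cat])
        v0 = gx.extract_features(template).values
        for _ in range(5):
            moved = template.transformed(lambda a: similarity(rng, a, out_of_plane=True))
            v1 = gx.extract_features(moved).values
            assert np.allclose(v0[idx3], v1[idx3], atol=1e-9)

    def test_2d_features_in_plane_invariant(self, template, rng):
        cat = builtin_catalog()
        idx2 = np.array([d.space == "2D" for d in cat])
        v0 = gx.extract_features(template).values
        for _ in range(5):
            moved = template.transformed(lambda a: similarity(rng, a, out_of_plane=False))
            v1 = gx.extract_features(moved).values
            assert np.allclose(v0[idx2], v1[idx2], atol=1e-9)

    def test_2d_features_break_under_out_of_plane_rotation(self, template):
        from scipy.spatial.transform import Rotation

        cat = builtin_catalog()
        idx2 = np.array([d.space == "2D" for d in cat])
        R = Rotation.from_euler("x", 35, degrees=True).as_matrix()
        v0 = gx.extract_features(template).values
        v1 = gx.extract_features(template.transformed(lambda a: a @ R.T)).values
        assert np.abs(v0[idx2] - v1[idx2]).max() > 1e-3

    def test_constructed_1d3_fixture(self, template):
        """1D3 = d(p1, p3)/d(p8, p9): place those four points so the value is 1."""
        arr = template.to_array()
        arr[0] = (0.0, 0.0, 0.0)   # p1
        arr[2] = (0.0, 2.0, 0.0)   # p3
        arr[7] = (5.0, 0.0, 0.0)   # p8
        arr[8] = (5.0, 2.0, 0.0)   # p9
        ls = gx.LandmarkSet.from_array(arr)
        fv = gx.extract_features(ls)
        assert fv.values[fv.ids.index("1D3")] == pytest.approx(1.0)

    def test_degenerate_arm_error_names_descriptor(self, template):
        arr = template.to_array()
        arr[1] = arr[0]  # p2 onto p1 breaks angle 1A3 (vertex p2)
        ls = gx.LandmarkSet.from_array(arr)
        with pytest.raises(ValueError, match="1A3"):
            gx.extract_features(ls)

    def test_matrix_row_permutation_only(self, small_faces):
        fm = gx.extract_matrix(small_faces)
        perm = np.random.default_rng(0).permutation(len(small_faces))
        fm_p = gx.extract_matrix([small_faces[i] for i in perm])
        assert fm_p.ids == fm.ids
        assert np.allclose(fm_p.X, fm.X[perm])
        assert np.array_equal(fm_p.y, fm.y[perm])

    def test_matrix_csv_round_trip(self, small_matrix, tmp_path):
        p = tmp_path / "features.csv"
        small_matrix.to_csv(p)
        again = gx.FeatureMatrix.from_csv(p)
        assert again.ids == small_matrix.ids
        assert np.allclose(again.X, small_matrix.X)
        assert np.array_equal(again.y, small_matrix.y)
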