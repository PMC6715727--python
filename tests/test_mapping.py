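import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microconnectome import mapping as mp
from microconnectome.atlas import make_planted_mapping, synth_projection_tensor


class TestBarycentricSystem:
    def test_anchor_coordinates_are_unit_vectors(self):
        sys_ = mp.BarycentricSystem([[0, 0], [1, 0], [0, 1]])
        np.testing.assert_allclose(sys_.to_bary(sys_.anchors), np.eye(3),
                                   atol=1e-12)

    def test_coordinates_sum_to_one(self, rng):
        sys_ = mp.BarycentricSystem(rng.random((3, 2)) * 100 + [[0, 0],
                                                                [50, 0],
                                                                [0, 50]])
        pts = rng.random((20, 2)) * 100
        np.testing.assert_allclose(sys_.to_bary(pts).sum(axis=1), 1.0)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            mp.BarycentricSystem([[0, 0], [1, 1], [2, 2]])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_to_from_bary(self, seed):
        r = np.random.default_rng(seed)
        sys_ = mp.BarycentricSystem(np.array([[0, 0], [80, 5], [10, 90]])
                                    + r.normal(0, 5, (3, 2)))
        pts = r.uniform(-50, 150, size=(10, 2))
        back = sys_.from_bary(sys_.to_bary(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestFitSourceAnchors:
    def test_equilateral_triangle_vertices_shrunk(self):
        # pixel triangle corners; centroid shrink by 25%
        mask = np.array([[0, 0], [8, 0], [4, 7]])
        # fill the triangle interior
        pts = []
        for i in range(9):
            for j in range(8):
                b = mp.BarycentricSystem([[0.5, 0.5], [8.5, 0.5], [4.5, 7.5]]
                                         ).to_bary([[i + 0.5, j + 0.5]])
                if (b >= -1e-9).all():
                    pts.append((i, j))
        mask = np.array(pts)
        sys_ = mp.fit_source_anchors(mask, pixel_size=1.0)
        centroid = (mask + 0.5).mean(axis=0)
        corners = np.array([[0.5, 0.5], [8.5, 0.5], [4.5, 7.5]])
        expected = corners + 0.25 * (centroid - corners)
        got = sys_.anchors[np.lexsort((sys_.anchors[:, 1], sys_.anchors[:, 0]))]
        exp = expected[np.lexsort((expected[:, 1], expected[:, 0]))]
        np.testing.assert_allclose(got, exp, atol=0.5)

    def test_hull_restricted_search_matches_brute_force(self, rng):
        from itertools import combinations
        mask = np.argwhere(np.ones((15, 15), dtype=bool))
        sys_ = mp.fit_source_anchors(mask, pixel_size=1.0, shrink=0.0)
        pts = (mask + 0.5).astype(float)
        best, best_val = None, -1
        for i, j, k in combinations(range(len(pts)), 3):
            tri = pts[[i, j, k]]
            val = (np.linalg.norm(tri[0] - tri[1])
                   + np.linalg.norm(tri[0] - tri[2])
                   + np.linalg.norm(tri[1] - tri[2]))
            if val > best_val:
                best_val, best = val, tri
        got_val = sum(np.linalg.norm(a - b)
                      for a, b in combinations(sys_.anchors, 2))
        assert got_val == pytest.approx(best_val)

    def test_two_pixel_mask_raises(self):
        with pytest.raises(ValueError):
            mp.fit_source_anchors(np.array([[0, 0], [1, 0]]))

    def test_collinear_mask_raises(self):
        with pytest.raises(ValueError):
            mp.fit_source_anchors(np.array([[0, 0], [1, 0], [2, 0], [3, 0]]))


class TestProjectionImages:
    def test_zero_tensor_gives_black_image(self, small_atlas):
        atlas, fm = small_atlas
        from microconnectome.atlas import VoxelProjectionTensor
        t = VoxelProjectionTensor(
            source_region=1, target_region=2, class_label="wt",
            source_voxels=atlas.region_voxels(1),
            target_pixels=atlas.region_footprint(2),
            strengths=np.zeros((len(atlas.region_voxels(1)),
                                len(atlas.region_footprint(2)))))
        src_sys = mp.fit_source_anchors(atlas.region_footprint(1),
                                        pixel_size=fm.pixel_size)
        img = mp.render_projection_image(t, src_sys, fm.pixel_size)
        assert (img.raw == 0).all()

    def test_low_saturation_voxel_contributes_nothing(self):
        from microconnectome.atlas import VoxelProjectionTensor
        sys_ = mp.BarycentricSystem([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        centroid_vox = np.array([[3, 3, 0]])  # flat (3.5, 3.5) ~ centroid
        t = VoxelProjectionTensor(
            source_region=1, target_region=2, class_label="wt",
            source_voxels=centroid_vox, target_pixels=np.array([[0, 0]]),
            strengths=np.array([[5.0]]))
        img = mp.render_projection_image(t, sys_, pixel_size=1.0)
        assert (img.raw == 0).all()

    def test_normalization_arithmetic(self):
        img = mp.ProjectionImage(pixels=np.array([[0, 0], [0, 1]]),
                                 raw=np.array([[0.2, 0.1, 0.1],
                                               [0.5, 0.3, 0.2]]))
        norm = mp.normalize_image(img)
        assert norm.sigma_tgt == pytest.approx(0.25)
        np.testing.assert_allclose(norm.colors[0], [0.5, 0.25, 0.25])
        np.testing.assert_allclose(norm.colors.sum(axis=1), [1.0, 1.0])

    def test_dim_pixel_fades_to_black(self):
        img = mp.ProjectionImage(pixels=np.array([[0, 0], [0, 1]]),
                                 raw=np.array([[1.0, 0.0, 0.0],
                                               [0.02, 0.01, 0.01]]))
        norm = mp.normalize_image(img)
        np.testing.assert_allclose(norm.colors[1], [0.08, 0.04, 0.04])
        assert norm.colors[1].sum() < 1

    def test_all_black_image_warns(self):
        img = mp.ProjectionImage(pixels=np.array([[0, 0]]),
                                 raw=np.zeros((1, 3)))
        with pytest.warns(UserWarning):
            norm = mp.normalize_image(img)
        assert (norm.colors == 0).all()


class TestRelativeError:
    def test_identical_images_zero(self, rng):
        m = rng.random((10, 3))
        assert mp.mapping_relative_error(m, m) == 0.0

    def test_two_pixel_oracle(self):
        m = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        n = np.array([[0.5, 0.5, 0.0], [0.0, 1.0, 0.0]])
        # sum |M-N| = 1.0; mean((M+N)/2) over 6 entries = 2/6... compute
        expected = 1.0 / np.mean((m + n) / 2) / 2
        assert mp.mapping_relative_error(m, n) == pytest.approx(expected)

    def test_symmetric(self, rng):
        m, n = rng.random((8, 3)), rng.random((8, 3))
        assert mp.mapping_relative_error(m, n) == pytest.approx(
            mp.mapping_relative_error(n, m))


class TestCharacterizeTransform:
    def _mapping(self, lin):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        tgt = src @ np.asarray(lin).T + 100.0
        return mp.TopographicMapping(source=mp.BarycentricSystem(src),
                                     target=mp.BarycentricSystem(tgt))

    def test_identity(self):
        out = mp.characterize_transform(self._mapping(np.eye(2)))
        assert out == {"reflection": False, "rotation_deg": 0}

    def test_mirror(self):
        out = mp.characterize_transform(self._mapping([[1, 0], [0, -1]]))
        assert out == {"reflection": True, "rotation_deg": 0}

    def test_rotation_90(self):
        out = mp.characterize_transform(self._mapping([[0, -1], [1, 0]]))
        assert out == {"reflection": False, "rotation_deg": 90}

    def test_rotation_with_mirror(self):
        rot = np.array([[0, -1], [1, 0]])
        out = mp.characterize_transform(
            self._mapping(rot @ np.diag([1, -1])))
        assert out == {"reflection": True, "rotation_deg": 90}


class TestMapSourceToTarget:
    def _pair(self, rng):
        src = mp.BarycentricSystem(np.array([[0, 0], [100, 10], [20, 90.0]]))
        tgt = mp.BarycentricSystem(np.array([[500, 0], [570, 40], [480, 95.0]]))
        return mp.TopographicMapping(source=src, target=tgt, kernel_width=30.0)

    def test_anchors_map_to_anchors(self, rng):
        m = self._pair(rng)
        out, width = mp.map_source_to_target(m.source.anchors, m)
        np.testing.assert_allclose(out, m.target.anchors, atol=1e-9)
        assert width == 30.0

    def test_matches_explicit_affine_transform(self, rng):
        m = self._pair(rng)
        # unique affine map from three point pairs
        src_h = np.column_stack([m.source.anchors, np.ones(3)])
        sol = np.linalg.solve(src_h, m.target.anchors)
        pts = rng.uniform(-100, 200, size=(25, 2))
        expect = np.column_stack([pts, np.ones(len(pts))]) @ sol
        got, _ = mp.map_source_to_target(pts, m)
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_round_trip_identity(self, rng):
        m = self._pair(rng)
        back = mp.TopographicMapping(source=m.target, target=m.source)
        pts = rng.uniform(0, 100, size=(10, 2))
        mapped, _ = mp.map_source_to_target(pts, m)
        again, _ = mp.map_source_to_target(mapped, back)
        np.testing.assert_allclose(again, pts, atol=1e-9)


class TestPlantedRecovery:
    def test_identity_mapping_recovered(self, small_atlas):
        atlas, fm = small_atlas
        m = make_planted_mapping(atlas, fm, 1, 2)
        base = pd.DataFrame([[0, 1.0], [0, 0]], index=[1, 2], columns=[1, 2])
        (t,) = synth_projection_tensor(atlas, fm, {(1, 2): m}, base,
                                       kernel_width=0.0, noise_sd=0.0, seed=0)
        img = mp.render_projection_image(t, m.source, fm.pixel_size)
        norm = mp.normalize_image(img)
        fitted, err = mp.fit_target_anchors(
            norm, atlas.region_footprint(2), m.source,
            atlas.region_footprint(1), fm.pixel_size, seed=0)
        assert np.abs(fitted.anchors - m.target.anchors).max() < fm.pixel_size
        assert err < 0.02

    def test_kernel_width_recovery_and_monotonicity(self, small_atlas):
        atlas, fm = small_atlas
        m0 = make_planted_mapping(atlas, fm, 1, 2)
        base = pd.DataFrame([[0, 1.0], [0, 0]], index=[1, 2], columns=[1, 2])
        widths = []
        for planted_w in (0.0, 150.0, 400.0):
            m = make_planted_mapping(atlas, fm, 1, 2, kernel_width=planted_w)
            (t,) = synth_projection_tensor(
                atlas, fm, {(1, 2): m}, base, kernel_width=planted_w,
                noise_sd=0.0, seed=0)
            img = mp.render_projection_image(t, m.source, fm.pixel_size)
            norm = mp.normalize_image(img)
            widths.append(mp.fit_kernel_width(norm, m0.target, fm.pixel_size))
        assert widths[0] <= widths[1] <= widths[2]
        assert widths[2] > widths[0]
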