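"""Feature tests: GLCM pair-counting oracle, shape closed forms, class gaps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.feature import graycoprops

from dermoscan.features import (
    FEATURE_NAMES,
    DegenerateShapeError,
    GlcmMatrix,
    area_of_object,
    asymmetry_index,
    border_irregularity,
    color_variance,
    compute_glcm,
    extract_feature_vector,
    glcm_statistics,
    lesion_diameter,
    perimeter,
    quantize,
    roundness,
)
from tests.conftest import disc_mask


def brute_force_glcm(gray, mask, offset, levels):
    """Independent scalar pair-counting oracle (symmetrized, normalized)."""
    q = (gray.astype(int) * levels) // 256
    h, w = gray.shape
    dx, dy = offset
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
    sym = counts + counts.T
    return sym / sym.sum()


class TestComputeGlcm:
    def test_constant_image_single_diagonal_entry(self):
        img = np.full((6, 6), 200, dtype=np.uint8)
        g = compute_glcm(img, levels=8)
        level = quantize(np.array([[200]]), 8)[0, 0]
        expected = np.zeros((8, 8))
        expected[level, level] = 1.0
        assert np.allclose(g.matrix, expected)

    def test_ramp_gives_uniform_off_diagonal(self):
        img = np.array([[0, 85, 170, 255]], dtype=np.uint8)
        g = compute_glcm(img, offset=(1, 0), levels=4)
        expected = np.zeros((4, 4))
        for i in range(3):  # pairs (0,1),(1,2),(2,3) symmetrized
            expected[i, i + 1] = expected[i + 1, i] = 1 / 6
        assert np.allclose(g.matrix, expected)

    @pytest.mark.parametrize("offset", [(1, 0), (0, 1), (1, 1), (1, -1)])
    def test_matches_pair_counting_oracle(self, offset):
        rng = np.random.default_rng(10)
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        mask = rng.random((8, 8)) > 0.25
        g = compute_glcm(img, mask, offset=offset, levels=8)
        assert np.allclose(g.matrix, brute_force_glcm(img, mask, offset, 8))

    def test_empty_mask_rejected(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            compute_glcm(img, np.zeros((4, 4), dtype=bool))

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            compute_glcm(np.zeros((4, 4), dtype=np.uint8), offset=(0, 0))


class TestGlcmStatistics:
    def test_degenerate_single_entry(self):
        m = np.zeros((8, 8))
        m[3, 3] = 1.0
        stats = glcm_statistics(GlcmMatrix(m, (1, 0), 8))
        assert stats["energy"] == 1.0
        assert stats["entropy"] == 0.0
        assert stats["contrast"] == 0.0
        assert stats["maximum_probability"] == 1.0

    def test_uniform_two_by_two(self):
        m = np.full((2, 2), 0.25)
        stats = glcm_statistics(GlcmMatrix(m, (1, 0), 2))
        assert stats["entropy"] == pytest.approx(2.0)  # log2(4) bits
        assert stats["energy"] == pytest.approx(0.25)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_statistics(GlcmMatrix(np.full((4, 4), 1.0), (1, 0), 4))

    @given(st.integers(0, 10_000))
    def test_ranges_on_random_glcms(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((8, 8))
        sym = raw + raw.T
        stats = glcm_statistics(GlcmMatrix(sym / sym.sum(), (1, 0), 8))
        assert 0 < stats["homogeneity"] <= 1
        assert 0 < stats["energy"] <= 1
        assert stats["entropy"] >= 0
        assert 0 < stats["inverse_difference_normalized"] <= 1
        assert 0 < stats["inverse_difference_moment_normalized"] <= 1
        assert -1 <= stats["correlation"] <= 1
        assert all(np.isfinite(v) for v in stats.values())

    def test_cross_check_against_skimage_graycoprops(self):
        """Contrast/dissimilarity/homogeneity/correlation/energy agree with the
        independent scikit-image implementation (index-shift invariant stats)."""
        rng = np.random.default_rng(11)
        raw = rng.random((8, 8))
        sym = raw + raw.T
        P = sym / sym.sum()
        stats = glcm_statistics(GlcmMatrix(P, (1, 0), 8))
        sk = P.reshape(8, 8, 1, 1)
        assert stats["contrast"] == pytest.approx(graycoprops(sk, "contrast")[0, 0])
        assert stats["dissimilarity"] == pytest.approx(graycoprops(sk, "dissimilarity")[0, 0])
        assert stats["homogeneity"] == pytest.approx(graycoprops(sk, "homogeneity")[0, 0])
        assert stats["correlation"] == pytest.approx(graycoprops(sk, "correlation")[0, 0])
        assert math.sqrt(stats["energy"]) == pytest.approx(graycoprops(sk, "energy")[0, 0])


def brute_force_asymmetry(mask, axis_vec, centroid):
    """Scalar reflect-and-count oracle for one axis."""
    coords = [tuple(p) for p in np.argwhere(mask)]
    ux, uy = axis_vec
    orig = set(coords)
    refl = set()
    for r, c in coords:
        dr, dc = r - centroid[0], c - centroid[1]
        proj = dr * ux + dc * uy
        rr = centroid[0] + 2 * proj * ux - dr
        rc = centroid[1] + 2 * proj * uy - dc
        refl.add((round(rr), round(rc)))
    delta = len(orig.symmetric_difference(refl)) / 2
    return 100.0 * delta / len(orig)


class TestAsymmetryIndex:
    def test_disc_is_nearly_symmetric(self):
        mask = disc_mask((120, 120), (60, 60), 40)
        assert asymmetry_index(mask).mean_pct < 2.0

    def test_notched_rectangle_matches_reflection_oracle(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[20:40, 20:60] = True  # 20 rows x 40 cols
        mask[20:30, 50:60] = False  # 10x10 corner notch
        result = asymmetry_index(mask)
        coords = np.argwhere(mask)
        centroid = coords.mean(axis=0)
        # principal axes of this flat shape are the coordinate axes
        from dermoscan.features import _principal_axes

        _, major, minor = _principal_axes(mask)
        assert result.major_pct == pytest.approx(
            brute_force_asymmetry(mask, tuple(major), centroid)
        )
        assert result.minor_pct == pytest.approx(
            brute_force_asymmetry(mask, tuple(minor), centroid)
        )
        assert result.mean_pct > 5.0  # the notch is clearly asymmetric

    def test_90_degree_rotation_invariance(self):
        from dermoscan.fixtures import LesionSpec, rasterize_lesion

        spec = LesionSpec(
            center=(64, 64), axes=(30, 18), rotation=20.0, boundary_wobble=0.25, wobble_lobes=7
        )
        mask = rasterize_lesion(spec, 128, 128)
        rotated = np.rot90(mask)
        a1 = asymmetry_index(mask).mean_pct
        a2 = asymmetry_index(rotated).mean_pct
        assert abs(a1 - a2) < 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            asymmetry_index(np.zeros((5, 5), dtype=bool))


class TestPerimeter:
    def test_square_matches_side_length_oracle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert perimeter(mask) == pytest.approx(36.0, abs=4.0)

    def test_disc_matches_closed_form(self):
        mask = disc_mask((120, 120), (60, 60), 40)
        assert perimeter(mask) == pytest.approx(2 * math.pi * 40, rel=0.03)

    def test_scales_linearly(self):
        small = disc_mask((120, 120), (60, 60), 20)
        big = disc_mask((120, 120), (60, 60), 40)
        assert perimeter(big) / perimeter(small) == pytest.approx(2.0, rel=0.03)


class TestBorderIrregularity:
    def test_disc_is_one(self):
        mask = disc_mask((120, 120), (60, 60), 40)
        assert border_irregularity(mask) == pytest.approx(1.0, abs=0.1)

    def test_wobble_increases_irregularity(self):
        from dermoscan.fixtures import LesionSpec, rasterize_lesion

        smooth = rasterize_lesion(
            LesionSpec(center=(80, 80), axes=(40, 40), boundary_wobble=0.0), 160, 160
        )
        wobbly = rasterize_lesion(
            LesionSpec(
                center=(80, 80), axes=(40, 40), boundary_wobble=0.3, wobble_lobes=7
            ),
            160,
            160,
        )
        assert border_irregularity(wobbly) > border_irregularity(smooth)

    def test_two_to_one_ellipse_matches_ramanujan_oracle(self):
        yy, xx = np.mgrid[0:160, 0:160]
        a, b = 60.0, 30.0
        mask = ((xx - 80) / a) ** 2 + ((yy - 80) / b) ** 2 <= 1
        h = ((a - b) / (a + b)) ** 2
        p_oracle = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        area = mask.sum()
        i_oracle = (2 * a * 2 * b) / (2 * math.pi * ((2 * a) ** 2 + (2 * b) ** 2)) * p_oracle**2 / area
        assert border_irregularity(mask) == pytest.approx(i_oracle, rel=0.05)

    def test_line_like_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 2:18] = True
        with pytest.raises(DegenerateShapeError):
            border_irregularity(mask)


class TestColorVariance:
    def test_single_color_zero_variance(self):
        img = np.full((10, 10, 3), (120, 60, 30), dtype=np.uint8)
        mask = np.ones((10, 10), dtype=bool)
        cv = color_variance(img, mask)
        assert cv.hue == pytest.approx(0.0, abs=1e-12)
        assert cv.saturation == pytest.approx(0.0, abs=1e-12)
        assert cv.value == pytest.approx(0.0, abs=1e-9)

    def test_two_value_levels_give_2500(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = 100  # gray: H=0, S=0, V=100
        img[1] = 200
        cv = color_variance(img, np.ones((2, 2), dtype=bool))
        assert cv.value == pytest.approx(2500.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
        mask = np.ones((6, 6), dtype=bool)
        cv1 = color_variance(img, mask)
        perm = rng.permutation(36)
        img2 = img.reshape(36, 3)[perm].reshape(6, 6, 3)
        cv2 = color_variance(img2, mask)
        assert cv1.hue == pytest.approx(cv2.hue)
        assert cv1.saturation == pytest.approx(cv2.saturation)
        assert cv1.value == pytest.approx(cv2.value)


class TestAreaDiameterRoundness:
    def test_area_examples(self):
        assert area_of_object(np.zeros((5, 5), dtype=bool)) == 0
        sq = np.zeros((60, 60), dtype=bool)
        sq[10:50, 10:50] = True
        assert area_of_object(sq) == 1600

    def test_disc_area_close_to_closed_form(self):
        mask = disc_mask((120, 120), (60, 60), 40)
        assert area_of_object(mask) == pytest.approx(math.pi * 40**2, rel=0.01)

    @given(st.integers(0, 5_000))
    def test_diameter_identity_exact(self, n_pixels):
        mask = np.zeros(10_000, dtype=bool)
        mask[:n_pixels] = True
        mask = mask.reshape(100, 100)
        assert lesion_diameter(mask) == math.sqrt(4 * n_pixels / math.pi)

    def test_disc_diameter(self):
        mask = disc_mask((120, 120), (60, 60), 40)
        assert lesion_diameter(mask) == pytest.approx(80.0, abs=1.0)

    def test_disc_roundness_is_one(self):
        mask = disc_mask((120, 120), (60, 60), 40)
        assert roundness(mask) == pytest.approx(1.0, abs=0.05)

    def test_square_roundness(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        assert roundness(mask) == pytest.approx(math.sqrt(math.pi / 4), abs=0.05)

    def test_elongated_rectangle_less_round_than_square(self):
        sq = np.zeros((60, 60), dtype=bool)
        sq[10:50, 10:50] = True
        rect = np.zeros((30, 140), dtype=bool)
        rect[11:19, 5:133] = True  # 8:1 aspect
        assert roundness(rect) < roundness(sq)

    def test_roundness_bounded_by_isoperimetric_inequality(self):
        rng = np.random.default_rng(13)
        from dermoscan.fixtures import LesionSpec, rasterize_lesion

        for _ in range(5):
            spec = LesionSpec(
                center=(64, 64),
                axes=(float(rng.uniform(15, 35)), float(rng.uniform(10, 30))),
                rotation=float(rng.uniform(0, 180)),
                boundary_wobble=float(rng.uniform(0, 0.3)),
                wobble_lobes=int(rng.integers(3, 9)),
            )
            assert roundness(rasterize_lesion(spec, 128, 128)) <= 1.1


class TestExtractFeatureVector:
    def test_length_names_and_determinism(self, small_dataset):
        from dermoscan.preprocess import to_grayscale

        s = small_dataset[0]
        gray = to_grayscale(s.image)
        v1 = extract_feature_vector(s.image, gray, s.truth_mask)
        v2 = extract_feature_vector(s.image, gray, s.truth_mask)
        assert list(v1.index) == FEATURE_NAMES
        assert len(v1) == 26
        assert np.array_equal(v1.to_numpy(), v2.to_numpy())
        assert np.isfinite(v1.to_numpy()).all()

    def test_malignant_shape_features_exceed_benign(self, roundness_dataset):
        asi_b, asi_m, irr_b, irr_m = [], [], [], []
        for s in roundness_dataset[:50] + roundness_dataset[100:150]:
            if s.spec.label == "benign":
                asi_b.append(asymmetry_index(s.truth_mask).mean_pct)
                irr_b.append(border_irregularity(s.truth_mask))
            else:
                asi_m.append(asymmetry_index(s.truth_mask).mean_pct)
                irr_m.append(border_irregularity(s.truth_mask))
        assert np.mean(asi_m) > np.mean(asi_b)
        assert np.mean(irr_m) > np.mean(irr_b)

    def test_nonfinite_feature_reported_by_name(self, small_dataset, monkeypatch):
        from dermoscan import features as feat
        from dermoscan.preprocess import to_grayscale

        monkeypatch.setattr(feat, "roundness", lambda mask: float("nan"))
        s = small_dataset[0]
        with pytest.raises(ValueError, match="roundness"):
            feat.extract_feature_vector(s.image, to_grayscale(s.image), s.truth_mask)

    def test_shape_mismatch_rejected(self, small_dataset):
        s = small_dataset[0]
        with pytest.raises(ValueError):
            extract_feature_vector(s.image, s.image[..., 0], s.truth_mask[:-1])
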