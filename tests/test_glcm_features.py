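"""GLCM construction conventions and the six texture features."""

import math

import numpy as np
import pytest

from sahmine.glcm_features import (
    ANGLES,
    GLCMParams,
    GLCMatrix,
    compute_features,
    compute_glcm,
    extract_image_features,
    normalize_glcm,
    preprocess_image,
    quantize_image,
    valid_pair_count,
)

WORKED_ROW = [[0, 1, 1, 0, 1, 2, 0, 2, 1]]


def brute_force_glcm(img, levels, dr, dc, counting):
    """Independent double-loop pair counter."""
    a = np.asarray(img)
    m = np.zeros((levels, levels), dtype=int)
    rows, cols = a.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                i, j = a[r, c], a[r2, c2]
                if counting == "unordered":
                    if i == j:
                        m[i, j] += 1
                    else:
                        m[i, j] += 1
                        m[j, i] += 1
                else:
                    m[i, j] += 1
                    m[j, i] += 1
    return m


def brute_force_features(p):
    """Independent double-loop evaluation of all six feature formulas."""
    L = p.shape[0]
    energy = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    entropy = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(L)
        for j in range(L)
        if p[i, j] > 0
    )
    p_i = [sum(p[i, j] for j in range(L)) for i in range(L)]
    p_j = [sum(p[i, j] for i in range(L)) for j in range(L)]
    mean = sum(i * p_i[i] for i in range(L))
    mu_j = sum(j * p_j[j] for j in range(L))
    stability = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    var_i = sum((i - mean) ** 2 * p_i[i] for i in range(L))
    var_j = sum((j - mu_j) ** 2 * p_j[j] for j in range(L))
    denom = math.sqrt(var_i) * math.sqrt(var_j)
    corr = (
        sum(
            (i - mean) * (j - mu_j) * p[i, j]
            for i in range(L)
            for j in range(L)
        )
        / denom
        if denom > 0
        else 0.0
    )
    return energy, contrast, entropy, mean, stability, corr


class TestQuantize:
    def test_full_range_identity_at_256_levels(self):
        img = np.arange(256).reshape(16, 16)
        assert (quantize_image(img, 256) == img).all()

    def test_constant_image_maps_to_zero(self):
        assert (quantize_image(np.full((4, 4), 117), 8) == 0).all()

    def test_eight_levels_match_floor_binning(self):
        img = np.arange(256).reshape(16, 16)
        assert (quantize_image(img, 8) == img * 8 // 256).all()
        assert quantize_image(img, 8).max() == 7


class TestComputeGLCM:
    def test_worked_single_row_example(self):
        m = compute_glcm(WORKED_ROW, GLCMParams(levels=3), 0)
        assert m.counts[1, 1] == 1
        assert m.counts[1, 2] == 2 and m.counts[2, 1] == 2

    def test_two_by_two_constant_diagonal_count(self):
        m = compute_glcm([[0, 0], [0, 0]], GLCMParams(levels=2), 0)
        assert m.counts[0, 0] == 2  # one pair per row, counted once each

    def test_symmetry_and_conservation_on_random_images(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            shape = (rng.integers(2, 12), rng.integers(2, 12))
            img = rng.integers(0, 6, size=shape)
            angle = int(rng.choice(ANGLES))
            for counting in ("unordered", "ordered-symmetric"):
                params = GLCMParams(levels=6, counting=counting)
                m = compute_glcm(img, params, angle)
                assert (m.counts == m.counts.T).all()
                npairs = valid_pair_count(shape, angle, 1)
                diag = int(np.trace(m.counts))
                if counting == "unordered":
                    # each unequal pair contributes 2 off-diagonal counts,
                    # each equal pair 1 diagonal count
                    assert (m.total - diag) % 2 == 0
                    assert diag + (m.total - diag) // 2 == npairs
                else:
                    assert m.total == 2 * npairs

    def test_matches_double_loop_counter(self):
        rng = np.random.default_rng(9)
        from sahmine.glcm_features import angle_offset

        for _ in range(25):
            img = rng.integers(0, 5, size=(7, 9))
            angle = int(rng.choice(ANGLES))
            for counting in ("unordered", "ordered-symmetric"):
                params = GLCMParams(levels=5, counting=counting)
                dr, dc = angle_offset(angle, 1)
                expect = brute_force_glcm(img, 5, dr, dc, counting)
                assert (compute_glcm(img, params, angle).counts == expect).all()

    def test_ordered_symmetric_agrees_with_skimage(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(3)
        img = rng.integers(0, 8, size=(16, 16), dtype=np.uint8)
        ours = compute_glcm(
            img, GLCMParams(levels=8, counting="ordered-symmetric"), 0
        ).counts
        ref = graycomatrix(img, [1], [0], levels=8, symmetric=True)[:, :, 0, 0]
        assert (ours == ref).all()

    def test_offset_exceeding_extent_raises(self):
        with pytest.raises(ValueError, match="extent"):
            compute_glcm([[0, 1]], GLCMParams(levels=2, distance=1), 90)


class TestNormalize:
    def test_probabilities_proportional_to_counts(self):
        m = compute_glcm(WORKED_ROW, GLCMParams(levels=3), 0)
        norm = normalize_glcm(m)
        assert norm.normalized.sum() == pytest.approx(1.0, abs=1e-12)
        assert norm.normalized[1, 2] == pytest.approx(2 / m.total)

    def test_single_cell(self):
        norm = normalize_glcm(GLCMatrix(counts=np.array([[4, 0], [0, 0]])))
        assert norm.normalized[0, 0] == 1.0

    def test_round_trip(self):
        m = compute_glcm(WORKED_ROW, GLCMParams(levels=3), 0)
        norm = normalize_glcm(m)
        rescaled = GLCMatrix(counts=(norm.normalized * m.total).round().astype(int))
        again = normalize_glcm(rescaled)
        assert np.allclose(again.normalized, norm.normalized)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError, match="zero pairs"):
            normalize_glcm(GLCMatrix(counts=np.zeros((3, 3), dtype=int)))


class TestFeatures:
    def test_degenerate_glcm(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        f = compute_features(p)
        assert f.energy == 1.0
        assert f.contrast == 0.0
        assert f.entropy == 0.0
        assert f.local_stability == 1.0
        assert f.correlation == 0.0  # flagged: zero-variance marginals

    def test_degenerate_correlation_can_raise(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            compute_features(p, degenerate_correlation="error")

    def test_uniform_glcm_entropy_and_energy(self):
        for L in (2, 4, 8):
            p = np.full((L, L), 1.0 / L ** 2)
            f = compute_features(p)
            assert f.entropy == pytest.approx(2 * math.log2(L), abs=1e-12)
            assert f.energy == pytest.approx(1.0 / L ** 2, abs=1e-15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            L = int(rng.integers(2, 9))
            raw = rng.random((L, L))
            raw = raw + raw.T  # symmetric like a real GLCM
            p = raw / raw.sum()
            f = compute_features(p)
            expected = brute_force_features(p)
            for got, want in zip(f.as_tuple(), expected):
                assert got == pytest.approx(want, abs=1e-10)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compute_features(np.ones((3, 3)))

    def test_energy_entropy_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            L = int(rng.integers(2, 8))
            p = rng.random((L, L))
            p /= p.sum()
            f = compute_features(p)
            assert 1.0 / L ** 2 <= f.energy <= 1.0
            assert 0.0 <= f.entropy <= 2 * math.log2(L) + 1e-12


class TestExtract:
    def test_transpose_swaps_0_and_90_degrees(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 64, size=(12, 12))
        p0 = GLCMParams(levels=8, angles=(0,))
        p90 = GLCMParams(levels=8, angles=(90,))
        f_img = extract_image_features(img, p0)
        f_t = extract_image_features(img.T, p90)
        assert f_img.as_tuple() == pytest.approx(f_t.as_tuple(), abs=1e-12)

    def test_single_angle_equals_direct_computation(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 200, size=(10, 10))
        params = GLCMParams(levels=8, angles=(45,))
        q = quantize_image(img, 8)
        direct = compute_features(normalize_glcm(compute_glcm(q, params, 45)))
        assert extract_image_features(img, params).as_tuple() == pytest.approx(
            direct.as_tuple()
        )

    def test_checkerboard_contrast_exceeds_constant(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255
        flat = np.full((8, 8), 128)
        params = GLCMParams(levels=4)
        assert (
            extract_image_features(board, params).contrast
            > extract_image_features(flat, params).contrast
        )

    def test_invariant_to_global_gray_shift(self):
        rng = np.random.default_rng(8)
        img = rng.integers(10, 90, size=(9, 9))
        params = GLCMParams(levels=8)
        f1 = extract_image_features(img, params)
        f2 = extract_image_features(img + 40, params)
        assert f1.as_tuple() == pytest.approx(f2.as_tuple(), abs=1e-12)


def test_preprocess_hooks():
    img = np.arange(100).reshape(10, 10)
    cropped = preprocess_image(img, center_crop=4)
    assert cropped.shape == (4, 4)
    denoised = preprocess_image(img, median_size=3)
    assert denoised.shape == img.shape
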