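"""Texture-module tests built around independent brute-force oracles."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from grapetex.exceptions import ContractError, EmptyPairError
from grapetex.segmentation import BinaryMask
from grapetex.texture import (
    CoMatrix,
    DEFAULT_OFFSETS,
    FEATURE_NAMES,
    compute_glcm,
    glcm_sequence,
    offset_step,
    quantize,
    texture_features,
    texture_map,
)

ANGLES = (0, 45, 90, 135)


def glcm_brute(q, offset, levels, symmetric, mask=None):
    """Naive double-loop pair counter: the independent oracle."""
    dr, dc = offset_step(offset)
    h, w = q.shape
    C = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dr, x + dc
            if not (0 <= y2 < h and 0 <= x2 < w):
                continue
            if mask is not None and not (mask[y, x] and mask[y2, x2]):
                continue
            C[q[y, x], q[y2, x2]] += 1
    if symmetric:
        C = C + C.T
    return C / C.sum()


def features_brute(P):
    """Term-by-term evaluation of the six statistics."""
    n = P.shape[0]
    contrast = dissim = homog = asm = 0.0
    for i in range(n):
        for j in range(n):
            contrast += P[i, j] * (i - j) ** 2
            dissim += P[i, j] * abs(i - j)
            homog += P[i, j] / (1 + (i - j) ** 2)
            asm += P[i, j] ** 2
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mu_i = sum(i * pi[i] for i in range(n))
    mu_j = sum(j * pj[j] for j in range(n))
    si = np.sqrt(sum(pi[i] * (i - mu_i) ** 2 for i in range(n)))
    sj = np.sqrt(sum(pj[j] * (j - mu_j) ** 2 for j in range(n)))
    if si * sj == 0:
        corr = 1.0
    else:
        corr = sum(
            P[i, j] * (i - mu_i) * (j - mu_j) for i in range(n) for j in range(n)
        ) / (si * sj)
    return np.array([contrast, dissim, homog, asm, np.sqrt(asm), corr])


class TestQuantize:
    def test_identity_at_256_levels(self, rng):
        g = rng.integers(0, 256, (8, 8)).astype(float)
        np.testing.assert_array_equal(quantize(g, 256), g.astype(int))

    def test_two_levels_split_at_128(self):
        g = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(g, 2)
        np.testing.assert_array_equal(q.ravel(), (np.arange(256) >= 128).astype(int))

    def test_constant_stays_constant(self):
        assert np.unique(quantize(np.full((5, 5), 200.0), 8)).size == 1

    def test_rejects_single_level(self):
        with pytest.raises(ContractError):
            quantize(np.zeros((4, 4)), 1)


class TestComputeGlcm:
    def test_worked_2x2_example(self):
        q = np.array([[0, 0], [1, 1]])
        M = compute_glcm(q, (1, 0), symmetric=True)
        assert M.P[0, 0] == 0.5 and M.P[1, 1] == 0.5
        assert M.P[0, 1] == 0.0 and M.P[1, 0] == 0.0

    def test_constant_image_single_entry(self):
        M = compute_glcm(np.full((4, 4), 3, dtype=int), (1, 45), levels=8)
        assert M.P[3, 3] == 1.0 and M.P.sum() == 1.0

    def test_too_small_image_raises(self):
        with pytest.raises(EmptyPairError):
            compute_glcm(np.zeros((2, 2), dtype=int), (5, 0))

    def test_mask_excluding_everything_raises(self):
        q = np.zeros((4, 4), dtype=int)
        with pytest.raises(EmptyPairError):
            compute_glcm(q, (1, 0), mask=np.zeros((4, 4)))

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_oracle_equivalence_random_images(self, symmetric, rng):
        """>=100 random trials against the double-loop counter."""
        for _ in range(104):
            h, w = rng.integers(4, 33, 2)
            levels = int(rng.integers(4, 17))
            q = rng.integers(0, levels, (h, w))
            angle = ANGLES[rng.integers(0, 4)]
            d = int(rng.integers(1, 3))
            M = compute_glcm(q, (d, angle), levels, symmetric)
            P_ref = glcm_brute(q, (d, angle), levels, symmetric)
            np.testing.assert_allclose(M.P, P_ref, atol=1e-10)

    def test_oracle_equivalence_with_mask(self, rng):
        for _ in range(25):
            q = rng.integers(0, 8, (12, 12))
            mask = (rng.random((12, 12)) > 0.3).astype(int)
            angle = ANGLES[rng.integers(0, 4)]
            M = compute_glcm(q, (1, angle), 8, True, BinaryMask(mask))
            np.testing.assert_allclose(
                M.P, glcm_brute(q, (1, angle), 8, True, mask), atol=1e-10
            )

    def test_matches_skimage_unmasked(self, rng):
        """Cross-check against an independent library implementation.

        skimage measures 45/135 degrees in the opposite row direction
        (toward increasing rows), so the diagonal angles swap; for symmetric
        matrices the two conventions then coincide pairwise.
        """
        q = rng.integers(0, 8, (16, 16))
        for angle, rad in zip(ANGLES, (0, 3 * np.pi / 4, np.pi / 2, np.pi / 4)):
            M = compute_glcm(q, (1, angle), 8, symmetric=True)
            ref = graycomatrix(
                q.astype(np.uint8), [1], [rad], levels=8, symmetric=True, normed=True
            )[:, :, 0, 0]
            np.testing.assert_allclose(M.P, ref, atol=1e-10)

    def test_symmetric_matrix_is_symmetric(self, rng):
        q = rng.integers(0, 6, (10, 10))
        M = compute_glcm(q, (1, 45), 6, symmetric=True)
        np.testing.assert_array_equal(M.P, M.P.T)


class TestTextureFeatures:
    def test_worked_two_entry_matrix(self):
        M = CoMatrix(np.diag([0.5, 0.5]), 2, (1, 0))
        f = texture_features(M)
        assert f.contrast == 0.0 and f.dissimilarity == 0.0
        assert f.homogeneity == 1.0
        assert f.asm == 0.5
        assert f.energy == pytest.approx(np.sqrt(0.5), abs=1e-15)
        assert f.correlation == pytest.approx(1.0, abs=1e-12)

    def test_single_entry_degenerate(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = texture_features(CoMatrix(P, 4, (1, 0)))
        assert (f.contrast, f.asm, f.energy, f.correlation) == (0.0, 1.0, 1.0, 1.0)

    def test_uniform_matrix_closed_form(self):
        n = 6
        f = texture_features(CoMatrix(np.full((n, n), 1 / n**2), n, (1, 0)))
        assert f.asm == pytest.approx(1 / n**2, abs=1e-12)
        assert f.correlation == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence_and_invariants(self, rng):
        for _ in range(100):
            levels = int(rng.integers(4, 17))
            q = rng.integers(0, levels, tuple(rng.integers(4, 33, 2)))
            angle = ANGLES[rng.integers(0, 4)]
            sym = bool(rng.integers(0, 2))
            M = compute_glcm(q, (1, angle), levels, sym)
            f = texture_features(M)
            np.testing.assert_allclose(
                f.as_vector(), features_brute(M.P), atol=1e-10
            )
            assert abs(f.energy**2 - f.asm) < 1e-12
            assert f.contrast >= f.dissimilarity
            assert abs(f.correlation) <= 1 + 1e-9

    def test_rotation_consistency(self, rng):
        """Rotating the image 90 degrees swaps the 0/90 (and 45/135) offsets."""
        q = rng.integers(0, 8, (12, 15))
        qr = np.rot90(q)
        for a, b in ((0, 90), (90, 0), (45, 135), (135, 45)):
            f1 = texture_features(compute_glcm(q, (1, a), 8, True))
            f2 = texture_features(compute_glcm(qr, (1, b), 8, True))
            np.testing.assert_allclose(f1.as_vector(), f2.as_vector(), atol=1e-12)


class TestGlcmSequence:
    def test_single_offset_matches_direct_call(self, rng):
        q = rng.integers(0, 8, (10, 10))
        seq = glcm_sequence(q, ((1, 90),), 8)
        direct = texture_features(compute_glcm(q, (1, 90), 8)).as_vector()
        np.testing.assert_array_equal(seq[0], direct)

    def test_default_offsets_give_length_8(self, rng):
        q = rng.integers(0, 8, (10, 10))
        assert glcm_sequence(q, DEFAULT_OFFSETS, 8).shape == (8, 6)

    def test_constant_image_identical_degenerate_vectors(self):
        seq = glcm_sequence(np.full((8, 8), 2, dtype=int), DEFAULT_OFFSETS, 8)
        np.testing.assert_array_equal(seq, np.tile(seq[0], (8, 1)))
        np.testing.assert_array_equal(seq[0], [0, 0, 1, 1, 1, 1])

    def test_empty_offsets_rejected(self):
        with pytest.raises(ContractError):
            glcm_sequence(np.zeros((4, 4), dtype=int), ())

    def test_isotropic_texture_angles_agree_softly(self, rng):
        g = rng.integers(0, 256, (96, 96)).astype(float)
        q = quantize(g, 8)
        seq = glcm_sequence(q, tuple((1, a) for a in ANGLES), 8)
        spread = np.abs(seq - seq.mean(axis=0)).max(axis=0)
        # same-distance vectors agree within sampling noise on iid texture
        assert (spread[:2] < 0.5).all() and (spread[2:] < 0.05).all()


class TestTextureMap:
    def test_constant_image_maps(self):
        maps = texture_map(np.full((8, 8), 100.0), window=3)
        np.testing.assert_array_equal(maps["contrast"], 0.0)
        np.testing.assert_array_equal(maps["homogeneity"], 1.0)

    def test_full_window_consistency(self, rng):
        g = rng.uniform(0, 255, (5, 5))
        q = quantize(g, 8)
        global_feats = texture_features(compute_glcm(q, (1, 0), 8)).as_vector()
        # a window covering the whole image must reproduce the global value
        # at the centre pixel (padding does not enter there)
        maps = texture_map(g, window=5, levels=8)
        centre = np.array([maps[n][2, 2] for n in FEATURE_NAMES])
        np.testing.assert_allclose(centre, global_feats, atol=1e-10)

    def test_two_band_image_contrast_localised(self):
        g = np.zeros((9, 12))
        g[:, 6:] = 200.0
        maps = texture_map(g, window=3, offset=(1, 0), levels=4)
        band = maps["contrast"][:, 5:7]
        outside = np.delete(maps["contrast"], [5, 6], axis=1)
        assert band.min() > 0.0
        np.testing.assert_array_equal(outside, 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ContractError):
            texture_map(np.zeros((6, 6)), window=4)
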