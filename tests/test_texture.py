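"""Texture catalogue tests, including brute-force oracles for every matrix family."""

import numpy as np
import pytest

from gliomics.texture import (
    GLSZM_FEATURES,
    OFFSETS_3D,
    TextureMatrixSet,
    _glcm_features,
    compute_texture_matrices,
    histogram_stats,
    quantize_roi,
    texture_feature_vector,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_glcm(levels, mask, Ng):
    counts = np.zeros((Ng, Ng))
    shape = levels.shape
    for p in np.argwhere(mask):
        for off in OFFSETS_3D:
            q = p + off
            if all(0 <= q[i] < shape[i] for i in range(3)) and mask[tuple(q)]:
                counts[levels[tuple(p)] - 1, levels[tuple(q)] - 1] += 1
    counts = counts + counts.T
    return counts / counts.sum() if counts.sum() else counts


def brute_glrlm(levels, mask, Ng):
    lab = np.where(mask, levels, 0)
    shape = lab.shape
    counts = np.zeros((Ng, max(shape)), dtype=int)
    for off in OFFSETS_3D:
        for p in np.argwhere(lab > 0):
            prev = p - off
            inside = all(0 <= prev[i] < shape[i] for i in range(3))
            if inside and lab[tuple(prev)] == lab[tuple(p)]:
                continue  # not a run start
            length = 1
            q = p + off
            while all(0 <= q[i] < shape[i] for i in range(3)) and lab[tuple(q)] == lab[tuple(p)]:
                length += 1
                q = q + off
            counts[lab[tuple(p)] - 1, length - 1] += 1
    return counts


def brute_glszm(levels, mask, Ng):
    lab = np.where(mask, levels, 0)
    shape = lab.shape
    seen = np.zeros(shape, dtype=bool)
    counts = np.zeros((Ng, int(mask.sum()) or 1), dtype=int)
    neighbors = [np.array(o) for o in OFFSETS_3D] + [-np.array(o) for o in OFFSETS_3D]
    for p in np.argwhere(lab > 0):
        p = tuple(p)
        if seen[p]:
            continue
        g = lab[p]
        stack, zone = [p], 0
        seen[p] = True
        while stack:
            q = stack.pop()
            zone += 1
            for off in neighbors:
                r = tuple(np.array(q) + off)
                if all(0 <= r[i] < shape[i] for i in range(3)) and not seen[r] and lab[r] == g:
                    seen[r] = True
                    stack.append(r)
        counts[g - 1, zone - 1] += 1
    return counts


def brute_ngtdm(levels, mask, Ng):
    s = np.zeros(Ng)
    n = np.zeros(Ng, dtype=int)
    shape = levels.shape
    offs = [np.array(o) for o in OFFSETS_3D] + [-np.array(o) for o in OFFSETS_3D]
    for p in np.argwhere(mask):
        vals = []
        for off in offs:
            q = p + off
            if all(0 <= q[i] < shape[i] for i in range(3)) and mask[tuple(q)]:
                vals.append(levels[tuple(q)])
        if vals:
            i = levels[tuple(p)] - 1
            s[i] += abs(levels[tuple(p)] - np.mean(vals))
            n[i] += 1
    return s, n


@pytest.mark.parametrize("seed", range(50))
def test_texture_matrices_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, 4, size=(5, 5, 5)).astype(np.int32)
    mask = rng.random((5, 5, 5)) > 0.3
    if not mask.any():
        mask[2, 2, 2] = True
    levels[~mask] = 0
    q = quantize_roi(levels.astype(float), mask, Ng=3)
    # quantization of the integer levels 1..3 maps them back onto 1..3
    m = compute_texture_matrices(q)
    assert np.allclose(m.glcm, brute_glcm(q.levels, q.levels > 0, 3), atol=1e-12)
    ref_rl = brute_glrlm(q.levels, q.levels > 0, 3)
    assert np.array_equal(m.glrlm[:, : ref_rl.shape[1]], ref_rl[:, : m.glrlm.shape[1]])
    ref_sz = brute_glszm(q.levels, q.levels > 0, 3)
    upto = min(m.glszm.shape[1], ref_sz.shape[1])
    assert np.array_equal(m.glszm[:, :upto], ref_sz[:, :upto])
    s_ref, n_ref = brute_ngtdm(q.levels, q.levels > 0, 3)
    assert np.allclose(m.ngtdm_s, s_ref, atol=1e-9)
    assert np.array_equal(m.ngtdm_n, n_ref)


class TestQuantization:
    def test_endpoints(self, rng):
        vals = rng.random((10, 10, 10))
        mask = np.ones(vals.shape, bool)
        q = quantize_roi(vals, mask, 32)
        assert q.levels[np.unravel_index(vals.argmin(), vals.shape)] == 1
        assert q.levels[np.unravel_index(vals.argmax(), vals.shape)] == 32

    def test_constant_roi_degenerate(self):
        q = quantize_roi(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool), 32)
        assert q.degenerate and set(np.unique(q.levels)) == {1}

    def test_affine_invariance(self, rng):
        vals = rng.random((8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.4
        mask[0, 0, 0] = True
        a = quantize_roi(vals, mask, 16).levels
        b = quantize_roi(2.5 * vals - 7.0, mask, 16).levels
        assert np.array_equal(a, b)


class TestFeatureVector:
    def test_checkerboard_glcm_hand_values(self):
        f = _glcm_features(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert f["energy"] == pytest.approx(0.5)
        assert f["inverse_difference_moment"] == pytest.approx(0.5)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_single_level_glcm(self):
        f = _glcm_features(np.array([[1.0]]))
        assert f["energy"] == 1.0 and f["contrast"] == 0.0

    def test_catalogue_has_41_unique_names(self, rng):
        levels = rng.integers(1, 5, size=(6, 6, 6)).astype(np.int32)
        q = quantize_roi(levels.astype(float), np.ones((6, 6, 6), bool), 4)
        vec = texture_feature_vector(compute_texture_matrices(q))
        assert len(vec) == 41
        assert len(set(vec)) == 41
        assert all(np.isfinite(v) for v in vec.values())

    def test_degenerate_glcm_zeroes_correlation_features(self):
        m = compute_texture_matrices(quantize_roi(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool), 8))
        vec = texture_feature_vector(m)
        assert vec["glcm.correlation"] == 0.0
        assert vec["glcm.imc1"] == 0.0 and vec["glcm.imc2"] == 0.0

    def test_single_voxel_roi_is_finite(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        q = quantize_roi(np.random.default_rng(0).random((5, 5, 5)), mask, 8)
        vec = texture_feature_vector(compute_texture_matrices(q))
        assert all(np.isfinite(v) for v in vec.values())


class TestHistogramStats:
    def test_uniform_eight_bins(self):
        # equal mass in 8 distinct values -> 8 occupied bins
        x = np.repeat(np.arange(8, dtype=float), 10).reshape(80, 1, 1)
        h = histogram_stats(x, np.ones(x.shape, bool))
        assert h["entropy"] == pytest.approx(3.0)
        assert h["energy"] == pytest.approx(0.125)

    def test_constant_roi_convention(self):
        h = histogram_stats(np.full((4, 4, 4), 2.0), np.ones((4, 4, 4), bool))
        assert h["variance"] == 0.0 and h["skewness"] == 0.0 and h["kurtosis"] == 0.0

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(10**5).reshape(-1, 1, 1)
        h = histogram_stats(x, np.ones(x.shape, bool))
        assert abs(h["skewness"]) <= 0.05
        assert abs(h["kurtosis"] - 3.0) <= 0.1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            histogram_stats(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))
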