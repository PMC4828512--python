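import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hipposeg import haralick as H
from hipposeg.errors import InvalidArgumentError


class TestGLCM:
    def test_constant_subimage_single_entry(self):
        P = H.glcm_matrix(np.full((3, 3), 4.2), levels=8, offset=(1, 0))
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_checkerboard_two_by_two(self):
        sub = np.array([[0.0, 1.0], [1.0, 0.0]])
        P = H.glcm_matrix(sub, levels=2, offset=(1, 0))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_symmetry_and_normalization(self, rng):
        sub = rng.normal(size=(6, 7))
        P = H.glcm_matrix(sub, levels=8, offset=(1, 0))
        assert P.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(P, P.T)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(arrays(float, (5, 5), elements=st.floats(-10, 10)))
    def test_entries_sum_to_one(self, sub):
        P = H.glcm_matrix(sub, levels=4, offset=(1, 0))
        assert P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            H.glcm_matrix(np.ones((1, 5)), levels=4, offset=(1, 0))
        with pytest.raises(InvalidArgumentError):
            H.glcm_matrix(np.ones((5, 1)), levels=4, offset=(0, 1))
        with pytest.raises(InvalidArgumentError):
            H.glcm_matrix(np.ones((3, 3)), levels=1, offset=(1, 0))

    def test_matches_skimage_accumulation(self, rng):
        # independent cross-check of the co-occurrence counting on the
        # already-quantized levels
        from skimage.feature import graycomatrix

        q = H.quantize(rng.normal(size=(7, 7)), 8).astype(np.uint8)
        ours = H.glcm_matrix(q.astype(float), levels=8, offset=(1, 0))
        # offset (1,0) = one step down the first axis -> skimage angle -90deg
        theirs = graycomatrix(q, distances=[1], angles=[-np.pi / 2], levels=8,
                              symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(ours, theirs, atol=1e-12)


class TestHaralickStats:
    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        energy, contrast, corr, idm = H.haralick_stats(P)
        assert (energy, contrast, corr, idm) == (1.0, 0.0, 0.0, 1.0)

    def test_checkerboard_glcm(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        energy, contrast, corr, idm = H.haralick_stats(P)
        assert energy == pytest.approx(0.5)
        assert contrast == pytest.approx(1.0)
        assert corr == pytest.approx(-1.0)
        assert idm == pytest.approx(0.5)

    def test_uniform_two_by_two(self):
        P = np.full((2, 2), 0.25)
        energy, contrast, corr, idm = H.haralick_stats(P)
        assert energy == pytest.approx(0.25)
        assert contrast == pytest.approx(0.5)
        assert corr == pytest.approx(0.0)
        assert idm == pytest.approx(0.75)

    def test_unnormalized_rejected(self):
        with pytest.raises(InvalidArgumentError):
            H.haralick_stats(np.ones((3, 3)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(arrays(float, (6, 6), elements=st.floats(-5, 5)))
    def test_stat_bounds(self, sub):
        P = H.glcm_matrix(sub, levels=8, offset=(1, 0))
        energy, contrast, corr, idm = H.haralick_stats(P)
        assert 0.0 < energy <= 1.0
        assert 0.0 < idm <= 1.0
        assert contrast >= 0.0
        assert -1.0 - 1e-9 <= corr <= 1.0 + 1e-9


class TestHaralickFeatures:
    def test_length_48(self, rng):
        vol = rng.normal(size=(11, 11, 11))
        assert H.haralick_features(vol, (5, 5, 5)).shape == (48,)

    def test_constant_volume_degenerate_values(self):
        out = H.haralick_features(np.full((11, 11, 11), 2.0), (5, 5, 5))
        out = out.reshape(12, 4)  # (size x projection) rows of 4 stats
        assert np.allclose(out[:, 0], 1.0)   # energy
        assert np.allclose(out[:, 1], 0.0)   # contrast
        assert np.allclose(out[:, 2], 0.0)   # correlation (degenerate)
        assert np.allclose(out[:, 3], 1.0)   # idm

    def test_hand_chain_for_n3(self, rng):
        # independent projection -> quantize -> count -> stats chain,
        # written with explicit loops
        vol = rng.normal(size=(9, 9, 9))
        v = (4, 4, 4)
        cube = vol[3:6, 3:6, 3:6]
        got = H.haralick_features(vol, v)[:12]
        col = 0
        for axis in range(3):
            sub = cube.mean(axis=axis)
            lo, hi = sub.min(), sub.max()
            q = np.minimum((sub - lo) / (hi - lo) * 8, 7).astype(int)
            counts = np.zeros((8, 8))
            for r in range(2):
                for c in range(3):
                    counts[q[r, c], q[r + 1, c]] += 1
                    counts[q[r + 1, c], q[r, c]] += 1
            P = counts / counts.sum()
            i = np.arange(8)
            energy = (P ** 2).sum()
            contrast = sum(
                (a - b) ** 2 * P[a, b] for a in i for b in i
            )
            mu = (i * P.sum(1)).sum()
            var = ((i - mu) ** 2 * P.sum(1)).sum()
            num = sum((a - mu) * (b - mu) * P[a, b] for a in i for b in i)
            corr = 0.0 if var <= 1e-12 else num / var
            idm = sum(P[a, b] / (1 + (a - b) ** 2) for a in i for b in i)
            assert got[col:col + 4] == pytest.approx(
                [energy, contrast, corr, idm], abs=1e-9)
            col += 4

    def test_batch_agrees_with_naive(self, rng):
        vol = rng.normal(size=(11, 11, 11)) * 30 + 100
        voxels = [(5, 5, 5), (0, 0, 0), (10, 3, 7), (10, 10, 10)]
        batch = H.haralick_features_batch(vol, np.array(voxels))
        ref = np.stack([H.haralick_features(vol, v) for v in voxels])
        assert np.max(np.abs(batch - ref)) < 1e-9

    def test_voxel_out_of_bounds(self):
        with pytest.raises(InvalidArgumentError):
            H.haralick_features(np.zeros((5, 5, 5)), (-1, 0, 0))
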