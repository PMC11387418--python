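"""THG demixing: features, autocontext, masking, uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triphoton import demix
from triphoton import synthetic as syn


@pytest.fixture(scope="module")
def textured_volume():
    """Two-region volume: smooth bright left half, speckled right half."""
    rng = np.random.default_rng(0)
    a = np.zeros((12, 24, 24), dtype=np.float32)
    a[:, :, :12] = 30.0
    a[:, :, 12:] = rng.uniform(0, 10, size=(12, 24, 12))
    return a


def _labels_two_class(n=60, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        z, y = rng.integers(1, 11), rng.integers(1, 23)
        rows.append([z, y, rng.integers(1, 11), 1])        # left: "vessel"
        rows.append([z, y, rng.integers(13, 23), 3])       # right: background
    return np.asarray(rows)


class TestUpsampleZ:
    def test_two_slices_span_linearly(self):
        a = np.zeros((2, 3, 3), dtype=np.float32)
        a[1] = 7.0
        up = demix.upsample_z(a, factor=4)
        assert up.shape == (8, 3, 3)
        np.testing.assert_allclose(up[:, 0, 0], 7.0 * np.linspace(0, 1, 8),
                                   rtol=1e-6)

    def test_constant_volume_unchanged(self):
        a = np.full((3, 4, 4), 2.5, dtype=np.float32)
        np.testing.assert_allclose(demix.upsample_z(a, 4), 2.5)

    def test_factor_one_is_identity(self):
        a = np.random.default_rng(0).normal(size=(3, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(demix.upsample_z(a, 1), a)

    def test_voxel_size_metadata_scales(self):
        from triphoton.volume import Volume
        v = Volume(np.zeros((2, 8, 8), np.float32), (4.0, 1.0, 1.0))
        up = demix.upsample_z(v, 4)
        assert up.voxel_size_um == (1.0, 1.0, 1.0)


class TestFeatures:
    def test_constant_volume_features(self):
        a = np.full((8, 12, 12), 5.0, dtype=np.float32)
        fs = demix.compute_features(a, scales=(1.0, 2.0))
        for name, plane in zip(fs.names, fs.data):
            if name == "raw" or name.startswith("gauss"):
                np.testing.assert_allclose(plane, 5.0, atol=5e-3)
            else:
                np.testing.assert_allclose(plane, 0.0, atol=5e-3)

    def test_single_bright_voxel_gradient_symmetric(self):
        a = np.zeros((9, 9, 9), dtype=np.float32)
        a[4, 4, 4] = 100.0
        fs = demix.compute_features(a, scales=(1.0,))
        gm = fs.data[fs.names.index("gradmag_s1")]
        assert gm[4, 4, 4] == pytest.approx(0.0, abs=1e-3)
        np.testing.assert_allclose(gm[4, 4, 3], gm[4, 4, 5], rtol=1e-5)
        np.testing.assert_allclose(gm[3, 4, 4], gm[5, 4, 4], rtol=1e-5)
        assert gm[4, 4, 5] > gm[4, 4, 8]

    def test_deterministic(self):
        a = np.random.default_rng(1).normal(
            size=(6, 10, 10)).astype(np.float32)
        f1 = demix.compute_features(a, scales=(0.7, 1.6))
        f2 = demix.compute_features(a, scales=(0.7, 1.6))
        np.testing.assert_array_equal(f1.data, f2.data)
        assert f1.names == f2.names


class TestUncertainty:
    def test_close_predictions_high_uncertainty(self):
        assert demix.uncertainty(np.array([0.51, 0.49, 0.0])) \
            == pytest.approx(0.98)

    def test_far_predictions_low_uncertainty(self):
        # 1 - (0.98 - 0.02): confident predictions are near-certain
        assert demix.uncertainty(np.array([0.98, 0.02])) \
            == pytest.approx(0.04)

    def test_uniform_probabilities_maximal(self):
        assert demix.uncertainty(np.array([1, 1, 1]) / 3.0) \
            == pytest.approx(1.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_invariant_to_class_ordering(self, p1, p2):
        rest = max(1.0 - p1 - p2, 0.0)
        p = np.array([p1, p2, rest])
        p /= p.sum() if p.sum() else 1.0
        base = demix.uncertainty(p)
        for perm in ([1, 0, 2], [2, 1, 0], [0, 2, 1]):
            assert demix.uncertainty(p[perm]) == pytest.approx(base)


class TestAutocontext:
    def test_separable_texture_high_training_accuracy(self, textured_volume):
        labels = _labels_two_class()
        bundle = demix.train_autocontext(textured_volume, labels, seed=0,
                                         scales=(0.7, 1.6), n_trees=30)
        fs = demix.compute_features(textured_volume, (0.7, 1.6))
        pred = bundle.stage1.predict(fs.at(labels[:, :3]))
        assert (pred == labels[:, 3]).mean() >= 0.99

    def test_seeded_training_reproducible(self, textured_volume):
        labels = _labels_two_class()
        b1 = demix.train_autocontext(textured_volume, labels, seed=3,
                                     scales=(0.7,), n_trees=10)
        b2 = demix.train_autocontext(textured_volume, labels, seed=3,
                                     scales=(0.7,), n_trees=10)
        p1 = demix.predict(b1, textured_volume)
        p2 = demix.predict(b2, textured_volume)
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_single_class_labels_rejected(self, textured_volume):
        labels = np.array([[1, 1, 1, 1], [2, 2, 2, 1]])
        with pytest.raises(ValueError, match="at least 2 classes"):
            demix.train_autocontext(textured_volume, labels)

    def test_stage2_uncertainty_not_higher(self, textured_volume):
        labels = _labels_two_class()
        bundle = demix.train_autocontext(textured_volume, labels, seed=0,
                                         scales=(0.7, 1.6), n_trees=30)
        fs1 = demix.compute_features(textured_volume, (0.7, 1.6))
        prob1 = demix._proba_full(bundle.stage1, fs1.matrix(),
                                  textured_volume.shape)
        u1 = demix.uncertainty(prob1).mean()
        u2 = demix.uncertainty(
            demix.predict(bundle, textured_volume).probs).mean()
        assert u2 <= u1 + 1e-6


class TestPredictionMask:
    def test_constant_denoised_forces_background(self, textured_volume):
        labels = _labels_two_class()
        bundle = demix.train_autocontext(textured_volume, labels, seed=0,
                                         scales=(0.7,), n_trees=10)
        pm = demix.predict(bundle, textured_volume,
                           denoised_up=np.zeros_like(textured_volume))
        assert np.all(pm.argmax_class == 3)
        assert np.all(pm.uncertainty_map() == 0.0)

    def test_all_foreground_mask_equals_unmasked(self, textured_volume):
        labels = _labels_two_class()
        bundle = demix.train_autocontext(textured_volume, labels, seed=0,
                                         scales=(0.7,), n_trees=10)
        pm_none = demix.predict(bundle, textured_volume)
        pm_all = demix.predict(bundle, textured_volume,
                               mask=np.ones(textured_volume.shape, bool))
        np.testing.assert_array_equal(pm_none.probs, pm_all.probs)

    def test_mask_reduces_false_positives(self):
        # noisy background speckles cause spurious structure calls that the
        # denoised-image mask removes
        scene = syn.make_scene(
            syn.SceneParams(shape=(16, 48, 48), n_vessels=1, n_fibers=2,
                            n_cells=0, seed=4),
            syn.NoiseParams(gaussian_sigma=20.0, seed=4))
        raw = scene.noisy_thg.data
        truth = scene.labels
        rng = np.random.default_rng(5)
        rows = []
        for cls, m in ((1, scene.vessel_mask), (2, scene.myelin_mask),
                       (3, scene.background_mask)):
            coords = np.argwhere(m)
            take = coords[rng.choice(len(coords), 80, replace=False)]
            rows.append(np.column_stack([take, np.full(len(take), cls)]))
        labels = np.vstack(rows)
        bundle = demix.train_autocontext(raw, labels, seed=0,
                                         scales=(1.0, 3.5), n_trees=30)
        from scipy import ndimage
        denoised = ndimage.gaussian_filter(raw, 1.5)
        pm_raw = demix.predict(bundle, raw)
        pm_msk = demix.predict(bundle, raw, denoised_up=denoised)
        bg = scene.background_mask
        fp_raw = (pm_raw.argmax_class[bg] != 3).sum()
        fp_msk = (pm_msk.argmax_class[bg] != 3).sum()
        assert fp_msk < fp_raw


class TestFeatureRanking:
    def test_indicator_feature_ranks_first_constant_last(self):
        rng = np.random.default_rng(0)
        shape = (4, 8, 8)
        cls = rng.integers(1, 4, size=shape)
        indicator = (cls == 1).astype(float) + 0.01 * rng.normal(size=shape)
        const = np.full(shape, 3.0)
        noise = rng.normal(size=shape)
        fs = demix.FeatureStack(
            data=np.stack([noise, const, indicator]).astype(np.float32),
            names=["noise", "const", "indicator"])
        ranked = demix.rank_discriminative_features(fs, cls, k=10)
        assert ranked[0][0] == "indicator"
        assert ranked[-1][0] == "const"
        assert ranked[-1][1] == pytest.approx(0.0, abs=1e-12)

    def test_k_clamped_to_feature_count(self):
        rng = np.random.default_rng(1)
        fs = demix.FeatureStack(
            data=rng.normal(size=(3, 2, 4, 4)).astype(np.float32),
            names=["a", "b", "c"])
        cls = rng.integers(1, 4, size=(2, 4, 4))
        assert len(demix.rank_discriminative_features(fs, cls, k=100)) == 3
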