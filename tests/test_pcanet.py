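import numpy as np
import pytest

from pcatrack.pcanet import (FilterStage, binary_hash,
                             block_histogram, block_starts, collect_patches,
                             convolve_stage, extract_feature, extract_features,
                             learn_filter_stage, learn_pcanet, load_model,
                             save_model)

from oracles import dense_eigenfilters, naive_block_histogram, naive_correlation, naive_hash


class TestCollectPatches:
    def test_single_window_mean_removed(self, rng):
        img = rng.uniform(size=(7, 7))
        cols = collect_patches(img, 7, 7)
        assert cols.shape == (49, 1)
        assert abs(cols[:, 0].sum()) < 1e-12

    def test_window_count(self, rng):
        cols = collect_patches(rng.uniform(size=(32, 32)), 7, 7)
        assert cols.shape == (49, 676)  # (32-7+1)^2

    def test_constant_image_gives_zeros(self):
        cols = collect_patches(np.full((10, 10), 0.3), 3, 3)
        assert np.all(cols == 0)

    def test_too_small_image(self):
        with pytest.raises(ValueError, match="smaller"):
            collect_patches(np.zeros((5, 5)), 7, 7)


class TestLearnFilterStage:
    def test_default_geometry(self, rng):
        stage = learn_filter_stage(rng.uniform(size=(6, 32, 32)), 7, 7, 8)
        assert stage.filters.shape == (8, 7, 7)

    def test_orthonormality(self, rng):
        stage = learn_filter_stage(rng.uniform(size=(4, 20, 20)), 5, 5, 6)
        flat = stage.filters.reshape(6, -1)
        gram = flat @ flat.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_matches_dense_oracle(self, rng):
        images = rng.uniform(size=(20, 16, 16))
        stage = learn_filter_stage(images, 5, 5, 4)
        expected = dense_eigenfilters(images, 5, 5, 4)
        assert np.abs(stage.filters - expected).max() < 1e-6

    def test_degenerate_data_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            learn_filter_stage([np.full((10, 10), 0.5)], 3, 3, 2)

    def test_too_many_filters(self, rng):
        with pytest.raises(ValueError):
            learn_filter_stage(rng.uniform(size=(2, 10, 10)), 3, 3, 10)


class TestConvolveStage:
    def test_zero_image(self, rng):
        stage = FilterStage(rng.standard_normal((3, 5, 5)))
        maps = convolve_stage(np.zeros((12, 12)), stage)
        assert len(maps) == 3 and all(np.all(m == 0) for m in maps)

    def test_delta_kernel_identity_interior(self, rng):
        delta = np.zeros((1, 5, 5))
        delta[0, 2, 2] = 1.0
        img = rng.uniform(size=(12, 12))
        (out,) = convolve_stage(img, FilterStage(delta))
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_matches_naive_correlation(self, rng):
        img = rng.standard_normal((10, 10))
        kern = rng.standard_normal((1, 3, 3))
        (out,) = convolve_stage(img, FilterStage(kern))
        np.testing.assert_allclose(out, naive_correlation(img, kern[0]), atol=1e-10)

    def test_output_keeps_shape(self, rng):
        stage = FilterStage(rng.standard_normal((2, 7, 7)))
        maps = convolve_stage(rng.uniform(size=(32, 32)), stage)
        assert all(m.shape == (32, 32) for m in maps)


class TestBinaryHash:
    def test_all_negative_gives_zero(self):
        maps = [-np.ones((4, 4))] * 5
        assert np.all(binary_hash(maps) == 0)

    def test_all_positive_gives_max_code(self):
        maps = [np.ones((4, 4))] * 8
        assert np.all(binary_hash(maps) == 255)

    def test_msb_convention(self):
        resp = [np.array([[0.5]]), np.array([[-0.2]]), np.array([[1.0]])]
        assert binary_hash(resp)[0, 0] == 5  # bits 101

    def test_zero_hashes_to_zero_bit(self):
        resp = [np.array([[0.0]]), np.array([[1.0]])]
        assert binary_hash(resp)[0, 0] == 1  # strict > 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            binary_hash([np.zeros((2, 2)), np.zeros((3, 3))])

    def test_matches_naive_oracle(self, rng):
        resp = list(rng.standard_normal((6, 9, 9)))
        np.testing.assert_array_equal(binary_hash(resp), naive_hash(resp))


class TestBlockHistogram:
    def test_mass_conservation_nonoverlapping(self, rng):
        codes = rng.integers(0, 16, size=(32, 32))
        hist = block_histogram(codes, 8, 0.0, n_bins=16)
        assert hist.shape == (16 * 16,)
        assert hist.sum() == 32 * 32
        assert np.all(hist.reshape(16, 16).sum(axis=1) == 64)

    def test_constant_map_delta_histogram(self):
        hist = block_histogram(np.full((16, 16), 3, dtype=int), 8, 0.0, n_bins=8)
        blocks = hist.reshape(4, 8)
        assert np.all(blocks[:, 3] == 64)
        assert blocks.sum() == 4 * 64

    def test_matches_naive_oracle_with_overlap(self, rng):
        codes = rng.integers(0, 8, size=(20, 20))
        for frac in (0.0, 0.5):
            got = block_histogram(codes, 6, frac, n_bins=8)
            np.testing.assert_array_equal(
                got, naive_block_histogram(codes, 6, frac, 8))

    def test_block_too_large(self):
        with pytest.raises(ValueError):
            block_histogram(np.zeros((4, 4), dtype=int), 8)

    def test_edge_anchored_final_block(self):
        # side 10, block 4, stride 4 -> starts 0, 4, then 6 anchored to edge
        assert block_starts(10, 4, 0.0) == [0, 4, 6]


class TestLearnPcanet:
    def test_default_two_stages(self, small_model):
        assert len(small_model.stages) == 2
        assert all(s.filters.shape == (8, 7, 7) for s in small_model.stages)

    def test_three_stage_variant(self, rng):
        model = learn_pcanet(rng.uniform(size=(6, 32, 32)), n_stages=3)
        assert len(model.stages) == 3
        assert model.n_code_maps == 64
        assert model.feature_dim == 64 * 16 * 256

    def test_duplicate_patch_invariance(self, rng):
        patch = rng.uniform(size=(32, 32))
        m1 = learn_pcanet([patch])
        m5 = learn_pcanet([patch] * 5)
        for s1, s5 in zip(m1.stages, m5.stages):
            np.testing.assert_allclose(s1.filters, s5.filters, atol=1e-8)

    def test_single_stage_rejected(self, rng):
        with pytest.raises(ValueError):
            learn_pcanet(rng.uniform(size=(3, 32, 32)), n_stages=1)


class TestExtractFeature:
    def test_default_dimension(self, small_model, rng):
        f = extract_feature(rng.uniform(size=(32, 32)), small_model)
        assert f.shape == (8 * 16 * 256,)  # L1 * m * 2^L2 = 32768
        assert small_model.feature_dim == 32768

    def test_determinism(self, small_model, rng):
        patch = rng.uniform(size=(32, 32))
        f1 = extract_feature(patch, small_model)
        f2 = extract_feature(patch.copy(), small_model)
        assert np.array_equal(f1, f2)

    def test_mass_depends_only_on_geometry(self, small_model, rng):
        for _ in range(3):
            f = extract_feature(rng.uniform(size=(32, 32)), small_model)
            assert f.sum() == 8 * 16 * 64  # L1 * m * block pixel count

    def test_batch_matches_single(self, small_model, rng):
        batch = rng.uniform(size=(4, 32, 32))
        feats = extract_features(batch, small_model)
        for i in range(4):
            assert np.array_equal(feats[i], extract_feature(batch[i], small_model))

    def test_interior_responses_offset_invariant(self, small_model, rng):
        # zero-mean filters null constant shifts wherever no zero padding leaks in
        patch = rng.uniform(0, 0.5, size=(32, 32))
        r1 = convolve_stage(patch, small_model.stages[0])
        r2 = convolve_stage(patch + 0.3, small_model.stages[0])
        for a, b in zip(r1, r2):
            np.testing.assert_allclose(a[3:-3, 3:-3], b[3:-3, 3:-3], atol=1e-10)

    def test_matches_composition_of_public_ops(self, small_model, rng):
        # the fused fast path must equal convolve -> hash -> histogram exactly
        patch = rng.uniform(size=(32, 32))
        fast = extract_features(patch[None], small_model, dtype=np.float64)[0]
        maps = convolve_stage(patch, small_model.stages[0])
        pieces = []
        for m in maps:
            resp = convolve_stage(m, small_model.stages[1])
            codes = binary_hash(resp)
            pieces.append(block_histogram(codes, small_model.block_size,
                                          small_model.block_overlap_fraction,
                                          n_bins=256))
        np.testing.assert_array_equal(fast, np.concatenate(pieces))

    def test_nonnegative_entries(self, small_model, rng):
        f = extract_feature(rng.uniform(size=(32, 32)), small_model)
        assert f.min() >= 0


class TestModelSerialization:
    def test_roundtrip(self, small_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_model(path, small_model)
        loaded, clf = load_model(path)
        assert clf is None
        patch = rng.uniform(size=(32, 32))
        assert np.array_equal(extract_feature(patch, loaded),
                              extract_feature(patch, small_model))

    def test_roundtrip_with_classifier(self, small_model, tmp_path, rng):
        from pcatrack.appearance import Classifier
        clf = Classifier(rng.standard_normal((small_model.feature_dim, 4)),
                         np.zeros(4), rng.standard_normal(4), 0.1,
                         input_scale=0.5)
        path = tmp_path / "model.npz"
        save_model(path, small_model, clf)
        _, back = load_model(path)
        assert np.array_equal(back.w1, clf.w1)
        assert back.b2 == clf.b2
        assert back.input_scale == clf.input_scale
        x = rng.uniform(size=small_model.feature_dim)
        assert back.scores(x[None])[0] == clf.scores(x[None])[0]
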