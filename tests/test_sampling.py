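"""Patch-geometry bookkeeping: the index arithmetic the whole method rests on."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sinoup import sampling as sm


class TestDownsample:
    def test_full_scale_regime(self):
        s = np.zeros((3601, 4))
        assert sm.downsample_sinogram(s, 40).shape[0] == 91

    def test_small_example_keeps_even_rows(self):
        s = np.arange(5)[:, None] * np.ones((1, 3))
        out = sm.downsample_sinogram(s, 2)
        assert np.array_equal(out[:, 0], [0, 2, 4])

    @given(st.integers(1, 200), st.integers(1, 60))
    def test_kept_indices_match_brute_force(self, T, k):
        s = np.arange(T)[:, None].astype(float)
        out = sm.downsample_sinogram(s, k)
        expected = [t for t in range(T) if t % k == 0]
        assert out[:, 0].astype(int).tolist() == expected
        assert out.shape[0] == (T - 1) // k + 1

    def test_invalid_factor(self):
        with pytest.raises(ValueError, match="positive integer"):
            sm.downsample_sinogram(np.zeros((5, 2)), 0)


class TestPatchGeometry:
    def test_patch_count_full_scale(self):
        assert sm.training_patch_starts(3601).size == 3200

    def test_too_short_sinogram_reports_minimum(self):
        with pytest.raises(ValueError, match="402"):
            sm.training_patch_starts(401)

    def test_input_offsets_default(self):
        assert sm.input_offsets().tolist() == list(range(0, 401, 40))

    def test_target_offsets_single_channel(self):
        assert sm.target_offsets(1).tolist() == [list(range(20, 381, 40))]

    def test_target_offsets_three_channels(self):
        # channels hold the 1st/2nd/3rd intermediate sub-position of each gap
        offs = sm.target_offsets(3)
        assert offs[0].tolist() == list(range(10, 371, 40))
        assert offs[1].tolist() == list(range(20, 381, 40))
        assert offs[2].tolist() == list(range(30, 391, 40))

    def test_gap_must_divide_by_factor(self):
        with pytest.raises(ValueError, match="divisible"):
            sm.target_offsets(3, gap=10)

    def test_ramp_sinogram_values_equal_row_indices(self):
        """Exhaustive index oracle on a ramp sinogram s[t, u] = t."""
        T = 450
        G = np.repeat(np.arange(T, dtype=float)[:, None], 3, axis=1)
        pairs = sm.extract_training_patches(G, n_out=3)
        assert len(pairs) == T - 401
        for pair in pairs[:: 16]:
            assert np.array_equal(pair.input[:, 0],
                                  pair.start + sm.input_offsets())
            for c in range(3):
                assert np.array_equal(pair.target[c, :, 0],
                                      pair.start + sm.target_offsets(3)[c])

    def test_training_inference_gap_match(self):
        """The inter-input spacing of a patch equals the row spacing after
        factor-``gap`` downsampling — the two regimes see the same angles."""
        gap = 40
        offs = sm.input_offsets(gap)
        assert set(np.diff(offs)) == {gap}
        kept = np.arange(0, 3601, gap)
        assert set(np.diff(kept)) == {gap}


class TestTileAndMerge:
    def test_single_window(self):
        u = np.random.default_rng(0).normal(size=(11, 5))
        windows, starts = sm.tile_inference_patches(u)
        assert windows.shape == (1, 11, 5)
        assert starts.tolist() == [0]

    def test_window_count_and_overlap(self):
        u = np.zeros((91, 3))
        windows, starts = sm.tile_inference_patches(u)
        assert len(starts) == 81
        assert np.array_equal(np.diff(starts), np.ones(80, dtype=int))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="11"):
            sm.tile_inference_patches(np.zeros((10, 4)))

    def test_merge_single_window_is_identity(self):
        pred = np.random.default_rng(1).normal(size=(1, 2, 10, 6)).astype(np.float32)
        out = sm.merge_patch_predictions(pred, np.array([0]), L=11)
        assert np.array_equal(out, pred[0])

    def test_merge_constant_predictions(self):
        preds = np.full((5, 1, 10, 4), 3.25)
        out = sm.merge_patch_predictions(preds, np.arange(5), L=15)
        assert np.allclose(out, 3.25)

    def test_merge_matches_brute_force(self, rng):
        """Per-pixel sum/count accumulation oracle on L=15."""
        L, W, n_out = 15, 7, 2
        starts = np.arange(L - 10)
        preds = rng.normal(size=(len(starts), n_out, 10, W)).astype(np.float64)
        out = sm.merge_patch_predictions(preds, starts, L)
        sums = np.zeros((n_out, L - 1, W))
        counts = np.zeros((n_out, L - 1, W))
        for p, s in zip(preds, starts):
            for g in range(10):
                sums[:, s + g] += p[:, g]
                counts[:, s + g] += 1
        assert np.allclose(out, sums / counts)

    def test_merge_missing_starts_error(self):
        preds = np.zeros((1, 1, 10, 3))
        with pytest.raises(ValueError, match="no window"):
            sm.merge_patch_predictions(preds, np.array([0]), L=15)


class TestInterlace:
    def test_row_counts_for_both_factors(self):
        u = np.zeros((91, 4))
        assert sm.interlace(u, np.zeros((1, 90, 4))).shape == (181, 4)
        assert sm.interlace(u, np.zeros((3, 90, 4))).shape == (361, 4)

    def test_inputs_pass_through_and_channels_ordered(self):
        L, W = 5, 3
        u = np.arange(L * W, dtype=float).reshape(L, W)
        mid = np.stack([np.full((L - 1, W), 100.0 + c) for c in range(3)])
        out = sm.interlace(u, mid)
        assert np.array_equal(out[::4], u)
        for c in range(3):
            assert np.all(out[c + 1::4] == 100.0 + c)

    @given(st.integers(11, 40), st.integers(1, 3), st.integers(1, 5))
    def test_downsample_inverts_interlace(self, L, n_out, W):
        rng = np.random.default_rng(L * 7 + n_out)
        u = rng.normal(size=(L, W))
        mid = rng.normal(size=(n_out, L - 1, W))
        out = sm.interlace(u, mid)
        assert np.array_equal(sm.downsample_sinogram(out, n_out + 1), u)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sm.interlace(np.zeros((5, 3)), np.zeros((1, 3, 3)))


class TestNormalization:
    def test_full_range_patch_gets_identity_params(self):
        x = np.array([[0.0, 0.5], [1.0, 0.25]])
        xn, params = sm.normalize_patch(x)
        assert params.offset == 0.0 and params.scale == 1.0
        assert np.array_equal(xn, x)

    def test_constant_patch_round_trip(self):
        x = np.full((4, 5), 2.5)
        xn, params = sm.normalize_patch(x)
        assert params.degenerate
        assert not xn.any()
        assert np.array_equal(sm.denormalize(xn, params), x)

    @given(st.integers(2, 8), st.integers(2, 8))
    def test_round_trip_property(self, h, w):
        x = np.random.default_rng(h * 31 + w).normal(0, 10, size=(h, w))
        xn, params = sm.normalize_patch(x)
        assert xn.min() >= 0.0 and xn.max() <= 1.0
        assert np.allclose(sm.denormalize(xn, params), x, atol=1e-6 * max(1, np.abs(x).max()))


class TestTrainingStream:
    def test_one_patch_per_sinogram_per_iteration(self, rng):
        sinos = [np.random.default_rng(i).normal(size=(420, 4)) for i in range(3)]
        stream = sm.iter_training_iterations(sinos, rng, n_out=1, minibatch=10)
        it, inputs, targets = next(stream)
        assert it == 0
        assert inputs.shape == (3, 11, 4)
        assert targets.shape == (3, 1, 10, 4)

    def test_balanced_usage_over_iterations(self):
        """Each sinogram is visited exactly once per iteration, 100 iterations."""
        sinos = [np.full((420, 2), float(i)) for i in range(4)]
        rng = np.random.default_rng(0)
        stream = sm.iter_training_iterations(sinos, rng, n_out=1, minibatch=3)
        per_iteration: dict[int, list[int]] = {}
        for it_idx, inputs, _ in stream:
            if it_idx >= 100:
                break
            per_iteration.setdefault(it_idx, []).extend(
                int(row[0, 0]) for row in inputs)
        assert len(per_iteration) == 100
        for visited in per_iteration.values():
            assert sorted(visited) == [0, 1, 2, 3]

    def test_seeded_determinism(self):
        sinos = [np.random.default_rng(i).normal(size=(410, 3)) for i in range(2)]
        def take(seed):
            stream = sm.iter_training_iterations(
                sinos, np.random.default_rng(seed), n_out=1, minibatch=10)
            return [next(stream)[1] for _ in range(5)]
        a, b = take(7), take(7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
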