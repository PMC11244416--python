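"""Reference network stages: hand oracles, soft-mask analytics, hard-mask
limit, fast-path equivalence, and checkpointing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpmask import _fast
from erpmask.model import (ModelConfig, ModelParams, channel_gap, classify,
                           dynamic_conv, extract_segment, feature_conv,
                           forward, load_checkpoint, mask_ratio,
                           masked_kernels, pad_input, save_checkpoint,
                           soft_mask)


def brute_conv_same3(S, w, b):
    """Direct-sum width-3 same-padded correlation, one channel at a time."""
    C, T = S.shape
    out = np.zeros((C, T))
    for c in range(C):
        for t in range(T):
            acc = 0.0
            for u in range(3):
                src = t + u - 1
                if 0 <= src < T:
                    acc += w[u] * S[c, src]
            out[c, t] = acc + b
    return out


def brute_valid_corr(x, kernel):
    """Brute-force valid correlation of a 1-D signal with a kernel."""
    lk = len(kernel)
    return np.array([np.dot(kernel, x[t:t + lk]) for t in range(len(x) - lk + 1)])


class TestFeatureConv:
    def test_identity_kernel(self):
        S = np.random.default_rng(0).normal(size=(3, 20))
        E = feature_conv(S, np.array([[0.0, 1.0, 0.0]]), np.zeros(1))
        np.testing.assert_allclose(E[0], S)

    def test_against_brute_force(self):
        rng = np.random.default_rng(1)
        S = np.arange(1.0, 6.0)[None, :]  # [1,2,3,4,5], one channel
        w = np.array([1.0, 0.0, 0.0])
        E = feature_conv(S, w[None], np.zeros(1))
        np.testing.assert_allclose(E[0], brute_conv_same3(S, w, 0.0))
        # and on random filters/signals
        S = rng.normal(size=(2, 15))
        W = rng.normal(size=(4, 3))
        b = rng.normal(size=4)
        E = feature_conv(S, W, b)
        for k in range(4):
            np.testing.assert_allclose(E[k], brute_conv_same3(S, W[k], b[k]),
                                       atol=1e-12)

    def test_k_feature_maps(self):
        S = np.zeros((4, 9))
        E = feature_conv(S, np.zeros((2, 3)), np.zeros(2))
        assert E.shape == (2, 4, 9)


class TestChannelGap:
    def test_constant_channels(self):
        E = np.full((2, 5, 7), 3.25)
        np.testing.assert_allclose(channel_gap(E), 3.25)

    def test_mean_and_shape(self):
        E = np.zeros((1, 2, 4))
        E[0, 0] = 1.0
        E[0, 1] = 3.0
        pooled = channel_gap(E)
        assert pooled.shape == (1, 1, 4)
        np.testing.assert_allclose(pooled, 2.0)


class TestExtractSegment:
    def test_full_slice(self):
        E = np.random.default_rng(0).normal(size=(2, 1, 10))
        np.testing.assert_array_equal(extract_segment(E, 0, 10), E)

    def test_slice_semantics(self):
        E = np.arange(10.0)[None, None, :]
        np.testing.assert_array_equal(extract_segment(E, 4, 3).ravel(),
                                      [4.0, 5.0, 6.0])

    def test_out_of_range(self):
        E = np.zeros((1, 1, 10))
        with pytest.raises(ValueError, match="out of range"):
            extract_segment(E, 8, 5)


class TestMaskRatio:
    def test_zero_weights_give_half(self):
        K, l = 3, 4
        L = np.random.default_rng(0).normal(size=(K, 1, l))
        W = np.random.default_rng(1).normal(size=(K, l))
        r = mask_ratio(L, W, np.zeros((l, 2 * l)), np.zeros(l), np.zeros(l), 0.0)
        np.testing.assert_allclose(r, 0.5)

    def test_monotone_in_output_bias(self):
        rng = np.random.default_rng(2)
        K, l = 2, 5
        L = rng.normal(size=(K, 1, l))
        W = rng.normal(size=(K, l))
        args = (rng.normal(size=(l, 2 * l)), rng.normal(size=l), rng.normal(size=l))
        r_values = [mask_ratio(L, W, *args, b2) for b2 in (-1.0, 0.0, 1.0, 3.0)]
        assert np.all(np.diff(np.array(r_values), axis=0) > 0)

    def test_hand_computation(self):
        # l=2, one scale: r = sigmoid(W_m2 (W_m1 (L ++ W) + b_m1) + b_m2)
        L = np.array([[0.5, -1.0]])
        W = np.array([[2.0, 0.25]])
        m1_w = np.array([[1.0, 0.0, -1.0, 2.0],
                         [0.5, 0.5, 0.5, 0.5]])
        m1_b = np.array([0.1, -0.2])
        m2_w = np.array([2.0, -1.0])
        m2_b = 0.3
        x = np.array([0.5, -1.0, 2.0, 0.25])
        h = m1_w @ x + m1_b
        expected = 1.0 / (1.0 + np.exp(-(m2_w @ h + m2_b)))
        r = mask_ratio(L, W, m1_w, m1_b, m2_w, m2_b)
        assert r[0] == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(3)
        K, l = 4, 6
        r = mask_ratio(rng.normal(size=(K, 1, l)), rng.normal(size=(K, l)),
                       rng.normal(size=(l, 2 * l)), rng.normal(size=l),
                       rng.normal(size=l), rng.normal())
        assert np.all((r > 0) & (r < 1))


class TestSoftMask:
    def test_half_at_ideal_length(self):
        M = soft_mask(np.array([0.5]), 10, 7.3)
        assert M[0, 4] == pytest.approx(0.5, abs=1e-15)  # j=5 (1-based) = l_i

    def test_spot_value(self):
        # lambda=5, l_i - j = 1 -> sigmoid(5)
        M = soft_mask(np.array([0.5]), 10, 5.0)
        assert M[0, 3] == pytest.approx(1.0 / (1.0 + np.exp(-5.0)), abs=1e-12)

    def test_large_sharpness_is_nearly_binary(self):
        M = soft_mask(np.array([0.35]), 10, 1000.0)
        assert np.all(M[0, :3] > 1 - 1e-6)
        assert np.all(M[0, 3:] < 1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(r=st.floats(0.01, 0.99), lam=st.floats(0.1, 4.0),
           l=st.integers(2, 8))
    def test_rows_strictly_decreasing_and_bounded(self, r, lam, l):
        # lam * l kept below ~35 so the logistic stays strictly inside (0, 1)
        # in float64; beyond that the mathematical strictness saturates
        M = soft_mask(np.array([r]), l, lam)
        assert np.all((M > 0) & (M < 1))
        assert np.all(np.diff(M[0]) < 0)


class TestKernelOpsAndConv:
    def test_masked_kernels(self):
        W = np.array([[2.0, -1.0], [0.5, 4.0]])
        np.testing.assert_array_equal(masked_kernels(W, np.ones_like(W)), W)
        np.testing.assert_array_equal(masked_kernels(W, np.zeros_like(W)), 0.0)
        assert masked_kernels(np.array([[2.0]]), np.array([[0.25]]))[0, 0] == 0.5
        with pytest.raises(ValueError, match="mismatch"):
            masked_kernels(W, np.ones((3, 2)))

    def test_pad_input(self):
        S = np.array([[1.0, 2.0, 3.0]])
        P = pad_input(S, 2)
        np.testing.assert_array_equal(P, [[1.0, 2.0, 3.0, 0.0, 0.0]])
        assert P.shape == (1, 5)

    def test_delta_kernel_reproduces_input(self):
        rng = np.random.default_rng(4)
        S = rng.normal(size=(3, 12))
        delta = np.zeros((2, 4))
        delta[:, 0] = 1.0
        D = dynamic_conv(pad_input(S, 4), delta, np.zeros(2))
        for i in range(2):
            np.testing.assert_allclose(D[i], S)

    def test_zero_kernel_gives_bias(self):
        S = np.random.default_rng(5).normal(size=(2, 10))
        D = dynamic_conv(pad_input(S, 3), np.zeros((1, 3)), np.array([1.5]))
        np.testing.assert_allclose(D, 1.5)

    def test_hard_binary_mask_equals_truncated_kernel(self):
        rng = np.random.default_rng(6)
        S = rng.normal(size=(2, 15))
        W = rng.normal(size=(1, 5))
        M = np.array([[1.0, 1.0, 1.0, 0.0, 0.0]])
        D = dynamic_conv(pad_input(S, 5), masked_kernels(W, M), np.zeros(1))
        for c in range(2):
            oracle = brute_valid_corr(np.concatenate([S[c], np.zeros(5)]), W[0, :3])
            np.testing.assert_allclose(D[0, c], oracle[:15], atol=1e-12)


class TestClassify:
    def test_zero_weights_give_bias(self, small_config, small_params):
        small_params.clf_w = np.zeros_like(small_params.clf_w)
        small_params.clf_b = np.asarray(2.5)
        D = np.random.default_rng(0).normal(
            size=(small_config.n_scales, small_config.n_channels,
                  small_config.n_samples))
        assert classify(D, small_params) == pytest.approx(2.5)

    def test_eval_mode_deterministic(self, small_config, small_params):
        D = np.random.default_rng(1).normal(
            size=(small_config.n_scales, small_config.n_channels,
                  small_config.n_samples))
        assert classify(D, small_params) == classify(D, small_params)

    def test_eval_mode_affine_in_D(self, small_config, small_params):
        rng = np.random.default_rng(2)
        shape = (small_config.n_scales, small_config.n_channels,
                 small_config.n_samples)
        D1, D2 = rng.normal(size=shape), rng.normal(size=shape)
        alpha = 0.3
        lhs = classify(alpha * D1 + (1 - alpha) * D2, small_params)
        rhs = (alpha * classify(D1, small_params)
               + (1 - alpha) * classify(D2, small_params))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestForward:
    def _input(self, cfg, seed=0):
        return np.random.default_rng(seed).normal(
            size=(cfg.n_channels, cfg.n_samples))

    def test_trace_shapes(self, small_config, small_params):
        cfg = small_config
        logit, trace, diag = forward(self._input(cfg), small_params)
        K, C, T, l = cfg.n_scales, cfg.n_channels, cfg.n_samples, cfg.kernel_len
        assert trace.E.shape == (K, C, T)
        assert trace.E_pooled.shape == (K, 1, T)
        assert trace.L.shape == (K, 1, l)
        assert trace.W_v.shape == (K, l)
        assert trace.S_padded.shape == (C, T + l)
        assert trace.D.shape == (K, C, T)
        assert np.isfinite(logit)
        assert diag.masks.shape == (K, l)
        assert np.all((diag.ratios > 0) & (diag.ratios < 1))
        assert np.all((diag.lengths > 0) & (diag.lengths < l))
        assert np.all(np.diff(diag.masks, axis=1) < 0)

    def test_standard_variant_ignores_mask_generator(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, variant="standard")
        rng = np.random.default_rng(3)
        params = ModelParams.initialize(cfg, rng)
        S = self._input(cfg, 4)
        logit1, _, diag = forward(S, params, cfg)
        assert diag is None
        params.m1_w = params.m1_w + 100.0
        params.m2_b = np.asarray(-50.0)
        params.feature_w = params.feature_w * -3.0
        logit2, _, _ = forward(S, params, cfg)
        assert logit1 == logit2

    def test_wrong_input_shape(self, small_config, small_params):
        with pytest.raises(ValueError, match="does not match"):
            forward(np.zeros((2, 2)), small_params, small_config)

    def test_mask_ratio_one_recovers_full_kernel_model(self, small_config):
        # continuity: pushing the generator output to r -> 1 with a sharp mask
        # converges to the standard full-length-kernel model.  Even in the
        # limit the mask's final entry is sigmoid(lambda*(l - l)) = 0.5, so the
        # last kernel tap stays half-weighted; equality therefore holds exactly
        # for kernels whose last tap is zero, which is what we assert.
        import dataclasses

        cfg = dataclasses.replace(small_config, sharpness=1000.0)
        rng = np.random.default_rng(5)
        params = ModelParams.initialize(cfg, rng)
        params.base_kernels[:, -1] = 0.0
        S = self._input(cfg, 6)
        std_cfg = dataclasses.replace(cfg, variant="standard")
        target, _, _ = forward(S, params, std_cfg)
        params.m2_b = np.asarray(80.0)  # saturates every ratio at ~1
        near, _, diag = forward(S, params, cfg)
        assert np.all(diag.ratios > 1 - 1e-12)
        assert near == pytest.approx(target, rel=1e-9)


class TestFastPathEquivalence:
    @pytest.mark.parametrize("variant", ["masked", "standard"])
    def test_batched_eval_matches_reference(self, small_config, small_params, variant):
        import dataclasses

        cfg = dataclasses.replace(small_config, variant=variant)
        X = np.random.default_rng(7).normal(size=(6, cfg.n_channels, cfg.n_samples))
        ref = np.array([forward(x, small_params, cfg)[0] for x in X])
        prep = _fast.prepare_data(X, cfg, dtype=np.float64)
        fast, _ = _fast.forward_batch(prep, np.arange(6), small_params, cfg,
                                      training=False)
        np.testing.assert_allclose(fast, ref, rtol=1e-10, atol=1e-10)

    def test_float32_path_close(self, small_config, small_params):
        X = np.random.default_rng(8).normal(size=(4, small_config.n_channels,
                                                  small_config.n_samples))
        ref = np.array([forward(x, small_params, small_config)[0] for x in X])
        prep = _fast.prepare_data(X, small_config, dtype=np.float32)
        fast, _ = _fast.forward_batch(prep, np.arange(4), small_params,
                                      small_config, training=False)
        np.testing.assert_allclose(fast, ref, rtol=1e-3, atol=1e-3)


class TestCheckpoint:
    def test_roundtrip(self, small_params, tmp_path):
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, small_params)
        back = load_checkpoint(path)
        for f in ModelParams.ARRAY_FIELDS:
            np.testing.assert_array_equal(getattr(back, f), getattr(small_params, f))
        assert back.config == small_params.config


class TestConfigValidation:
    def test_segment_out_of_range(self):
        cfg = ModelConfig(n_scales=2, kernel_len=50, segment_start=60,
                          n_channels=2, n_samples=100)
        with pytest.raises(ValueError, match="segment"):
            cfg.validate()

    def test_bad_variant(self):
        cfg = ModelConfig(variant="other")
        with pytest.raises(ValueError, match="variant"):
            cfg.validate()
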