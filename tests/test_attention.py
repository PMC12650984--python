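"""Attention operators vs hand-unrolled oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brixnet.attention import (
    ChannelAttentionLayer,
    ChannelAttentionState,
    SpatialAttentionLayer,
    SpatialAttentionState,
    adaptive_max_pool,
    apply_channel_attention,
    apply_spatial_attention,
    channel_attention,
    channel_pool,
    spatial_attention,
    spatial_pool,
)

from conftest import nudge_biases


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _random_channel_state(rng, c, c_prev=None, r=2):
    h = max(c // r, 1)
    st_ = ChannelAttentionState(
        w1=rng.normal(size=(c, h)),
        b1=rng.normal(size=h),
        w2=rng.normal(size=(h, c)),
        b2=rng.normal(size=c),
        lambda1=float(rng.uniform(0.5, 1.5)),
        lambda2=float(rng.uniform(0.5, 1.5)),
        lambda3=float(rng.uniform(0.5, 1.5)),
    )
    if c_prev is not None:
        st_.w0 = rng.normal(size=(c_prev, c))
        st_.b0 = rng.normal(size=c)
        st_.bn_gamma = rng.uniform(0.5, 1.5, c)
        st_.bn_beta = rng.normal(size=c)
        st_.bn_mean = rng.normal(size=c) * 0.1
        st_.bn_var = rng.uniform(0.5, 1.5, c)
    return st_


def oracle_channel_attention(f, prev, state):
    """Element-by-element transcription of the weighted-fusion formula."""
    h_, w_, c = f.shape

    def mlp(v):
        hidden = np.zeros(state.w1.shape[1])
        for j in range(state.w1.shape[1]):
            acc = state.b1[j]
            for i in range(c):
                acc += v[i] * state.w1[i, j]
            hidden[j] = max(acc, 0.0)
        out = np.zeros(c)
        for i in range(c):
            acc = state.b2[i]
            for j in range(state.w1.shape[1]):
                acc += hidden[j] * state.w2[j, i]
            out[i] = acc
        return out

    m_avg = np.zeros(c)
    m_max = np.full(c, -np.inf)
    for ch in range(c):
        for i in range(h_):
            for j in range(w_):
                m_avg[ch] += f[i, j, ch]
                m_max[ch] = max(m_max[ch], f[i, j, ch])
        m_avg[ch] /= h_ * w_
    s = state.lambda1 * mlp(m_avg) + state.lambda2 * mlp(m_max)
    if prev is not None:
        t = np.zeros(c)
        for i in range(c):
            acc = state.b0[i]
            for j in range(prev.shape[0]):
                acc += prev[j] * state.w0[j, i]
            t[i] = state.bn_gamma[i] * (acc - state.bn_mean[i]) / np.sqrt(
                state.bn_var[i] + 1e-5
            ) + state.bn_beta[i]
            t[i] = max(t[i], 0.0)
        s = s + state.lambda3 * mlp(t)
    return 1.0 / (1.0 + np.exp(-s))


def oracle_spatial_attention(f, prev, state):
    h_, w_, c = f.shape
    p_avg = np.zeros((h_, w_))
    p_max = np.full((h_, w_), -np.inf)
    for i in range(h_):
        for j in range(w_):
            for ch in range(c):
                p_avg[i, j] += f[i, j, ch]
                p_max[i, j] = max(p_max[i, j], f[i, j, ch])
            p_avg[i, j] /= c
    planes = [p_avg, p_max]
    if prev is not None:
        k = state.wl.shape[0]
        pad = k // 2
        t = np.zeros((h_, w_))
        for i in range(h_):
            for j in range(w_):
                acc = state.bl[0]
                for a in range(k):
                    for b in range(k):
                        ii, jj = i + a - pad, j + b - pad
                        if 0 <= ii < h_ and 0 <= jj < w_:
                            acc += prev[ii, jj] * state.wl[a, b, 0, 0]
                t[i, j] = acc
        planes.append(t)
    k = state.ws.shape[0]
    pad = k // 2
    out = np.zeros((h_, w_))
    for i in range(h_):
        for j in range(w_):
            acc = state.bs[0]
            for a in range(k):
                for b in range(k):
                    ii, jj = i + a - pad, j + b - pad
                    if 0 <= ii < h_ and 0 <= jj < w_:
                        for p, plane in enumerate(planes):
                            acc += plane[ii, jj] * state.ws[a, b, p, 0]
            out[i, j] = 1.0 / (1.0 + np.exp(-acc))
    return out


class TestPooling:
    def test_constant_tensor(self):
        f = np.full((3, 4, 2), 3.0)
        m_avg, m_max = channel_pool(f)
        assert np.array_equal(m_avg, [3.0, 3.0]) and np.array_equal(m_max, [3.0, 3.0])
        p_avg, p_max = spatial_pool(f)
        assert np.all(p_avg == 3.0) and np.all(p_max == 3.0)

    def test_single_pixel_and_single_channel(self, rng):
        f = rng.normal(size=(1, 1, 5))
        m_avg, m_max = channel_pool(f)
        assert np.array_equal(m_avg, f[0, 0]) and np.array_equal(m_max, f[0, 0])
        g = rng.normal(size=(3, 3, 1))
        p_avg, p_max = spatial_pool(g)
        assert np.array_equal(p_avg, g[..., 0]) and np.array_equal(p_max, g[..., 0])

    def test_matches_loop_oracle(self, rng):
        f = rng.normal(size=(4, 4, 3))
        m_avg, m_max = channel_pool(f)
        for c in range(3):
            vals = [f[i, j, c] for i in range(4) for j in range(4)]
            assert abs(m_avg[c] - sum(vals) / 16) < 1e-12
            assert m_max[c] == max(vals)

    def test_empty_tensor_rejected(self):
        with pytest.raises(ValueError):
            channel_pool(np.zeros((0, 2, 2)))
        with pytest.raises(ValueError):
            spatial_pool(np.zeros((2, 2, 0)))


class TestChannelAttention:
    def test_zero_parameters_give_half(self):
        f = np.random.default_rng(0).normal(size=(3, 3, 4))
        state = ChannelAttentionState.zeros(4)
        assert np.allclose(channel_attention(f, None, state), 0.5, atol=1e-15)

    def test_spatial_permutation_invariance(self, rng):
        f = rng.normal(size=(4, 4, 3))
        state = _random_channel_state(rng, 3)
        w1 = channel_attention(f, None, state)
        perm = rng.permutation(16)
        f2 = f.reshape(16, 3)[perm].reshape(4, 4, 3)
        assert np.allclose(w1, channel_attention(f2, None, state), atol=1e-12)

    @pytest.mark.parametrize("with_prev", [False, True])
    def test_matches_hand_unrolled_oracle(self, rng, with_prev):
        f = rng.normal(size=(2, 2, 3))
        prev = rng.uniform(0.2, 0.8, size=4) if with_prev else None
        state = _random_channel_state(rng, 3, c_prev=4 if with_prev else None)
        got = channel_attention(f, prev, state)
        want = oracle_channel_attention(f, prev, state)
        assert np.allclose(got, want, atol=1e-10)
        assert np.all((got > 0) & (got < 1))

    def test_apply_identity_zero_and_oracle(self, rng):
        f = rng.normal(size=(3, 3, 4))
        assert np.array_equal(apply_channel_attention(f, np.ones(4)), f)
        assert not apply_channel_attention(f, np.zeros(4)).any()
        w = rng.uniform(size=4)
        out = apply_channel_attention(f, w)
        for i in range(3):
            for j in range(3):
                for c in range(4):
                    assert out[i, j, c] == f[i, j, c] * w[c]

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_channel_attention(rng.normal(size=(2, 2, 3)), np.ones(4))
        state = _random_channel_state(rng, 3, c_prev=4)
        with pytest.raises(ValueError):
            channel_attention(rng.normal(size=(2, 2, 3)), np.ones(5), state)


class TestSpatialAttention:
    def test_zero_parameters_give_half(self):
        f = np.random.default_rng(0).normal(size=(4, 4, 3))
        state = SpatialAttentionState.zeros(first_layer=True)
        assert np.allclose(spatial_attention(f, None, state), 0.5, atol=1e-15)

    def test_channel_permutation_invariance(self, rng):
        f = rng.normal(size=(4, 4, 5))
        state = SpatialAttentionState(
            ws=rng.normal(size=(7, 7, 2, 1)), bs=rng.normal(size=1)
        )
        m1 = spatial_attention(f, None, state)
        m2 = spatial_attention(f[:, :, rng.permutation(5)], None, state)
        # the max path is exact; the mean path reorders float summation
        assert np.allclose(m1, m2, atol=1e-12)

    @pytest.mark.parametrize("with_prev", [False, True])
    def test_matches_hand_unrolled_oracle(self, rng, with_prev):
        f = rng.normal(size=(4, 4, 3))
        state = SpatialAttentionState(
            ws=rng.normal(size=(3, 3, 3 if with_prev else 2, 1)),
            bs=rng.normal(size=1),
            wl=rng.normal(size=(3, 3, 1, 1)) if with_prev else None,
            bl=rng.normal(size=1) if with_prev else None,
        )
        prev = rng.uniform(0.2, 0.8, size=(4, 4)) if with_prev else None
        got = spatial_attention(f, prev, state)
        want = oracle_spatial_attention(f, prev, state)
        assert np.allclose(got, want, atol=1e-10)
        assert np.all((got > 0) & (got < 1))

    def test_apply_identity_indicator_and_oracle(self, rng):
        f = rng.normal(size=(3, 3, 2))
        assert np.array_equal(apply_spatial_attention(f, np.ones((3, 3))), f)
        ind = np.zeros((3, 3))
        ind[1, 2] = 1.0
        out = apply_spatial_attention(f, ind)
        assert np.array_equal(out[1, 2], f[1, 2]) and out.sum() == f[1, 2].sum()
        m = rng.uniform(size=(3, 3))
        out = apply_spatial_attention(f, m)
        for i in range(3):
            for j in range(3):
                assert np.allclose(out[i, j], f[i, j] * m[i, j], atol=1e-15)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_spatial_attention(rng.normal(size=(3, 3, 2)), np.ones((2, 3)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_attention_outputs_always_in_unit_interval(seed):
    # strictly inside (0,1) at moderate activations; the sigmoid saturates to
    # exactly 0/1 in floating point once its argument passes ~37, so extreme
    # inputs are only required to stay inside the closed interval
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(3, 3, 4))
    cstate = _random_channel_state(rng, 4)
    w = channel_attention(f, None, cstate)
    assert np.all((w > 0) & (w < 1))
    sstate = SpatialAttentionState(
        ws=rng.normal(size=(7, 7, 2, 1)), bs=rng.normal(size=1)
    )
    m = spatial_attention(f, None, sstate)
    assert np.all((m > 0) & (m < 1))
    extreme = spatial_attention(f * 1e6, None, sstate)
    assert np.all((extreme >= 0) & (extreme <= 1))


class TestLayerVsFunctional:
    def test_channel_layer_matches_functional_state_export(self, rng):
        lay0 = ChannelAttentionLayer(3, rng, None, r=2)
        lay1 = ChannelAttentionLayer(4, rng, c_prev=3, r=2)
        nudge_biases(lay0.params() + lay1.params(), rng)
        f0 = rng.normal(size=(1, 3, 3, 3))
        out0, w0 = lay0.forward(f0, None, training=False)
        func_w0 = channel_attention(f0[0], None, lay0.export_state())
        assert np.allclose(w0[0], func_w0, atol=1e-12)
        f1 = rng.normal(size=(1, 3, 3, 4))
        _, w1 = lay1.forward(f1, w0, training=False)
        func_w1 = channel_attention(f1[0], w0[0], lay1.export_state())
        assert np.allclose(w1[0], func_w1, atol=1e-12)

    def test_spatial_layer_matches_functional_state_export(self, rng):
        lay = SpatialAttentionLayer(rng, first_layer=True)
        f = rng.normal(size=(1, 5, 5, 3))
        _, m = lay.forward(f, None, training=False)
        func_m = spatial_attention(f[0], None, lay.export_state())
        assert np.allclose(m[0], func_m, atol=1e-12)


class TestGradientFlow:
    def test_all_lambda_coefficients_receive_gradient(self, rng):
        from brixnet.models import build_model
        from brixnet.experiments import desk_spec

        spec = desk_spec("ma-cnn")
        model = build_model(spec, n_bands=6, seed=0)
        nudge_biases(model, rng)
        xs = rng.normal(size=(4, 3, 3, 6))
        xp = rng.normal(size=(4, 9, 9, 6))
        for p in model.params():
            p.grad[...] = 0.0
        model.forward(xs, xp, training=True)
        model.backward(rng.normal(size=4))
        lambdas = [p for p in model.params() if "lambda" in p.name]
        assert len(lambdas) == 8  # 2 at the first block, 3 at each deeper block
        for p in lambdas:
            assert float(np.abs(p.grad)) > 0, p.name

    def test_layer_backward_matches_finite_differences(self, rng):
        lay = ChannelAttentionLayer(4, rng, c_prev=3, r=2)
        nudge_biases(lay.params(), rng)
        f = rng.normal(size=(2, 3, 3, 4))
        prev = rng.uniform(0.2, 0.8, size=(2, 3))
        w = rng.normal(size=(2, 3, 3, 4))

        def loss():
            out, _ = lay.forward(f, prev, training=True)
            return float(np.sum(w * out))

        for p in lay.params():
            p.grad[...] = 0.0
        out, _ = lay.forward(f, prev, training=True)
        lay.backward(w, None)
        for p in lay.params():
            it = np.nditer(p.value, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p.value[i]
                p.value[i] = orig + 1e-6
                fp = loss()
                p.value[i] = orig - 1e-6
                fm = loss()
                p.value[i] = orig
                assert np.isclose((fp - fm) / 2e-6, p.grad[i], rtol=1e-4, atol=1e-7), p.name


def test_adaptive_max_pool_oracle(rng):
    x = rng.normal(size=(2, 7, 7, 3))
    y, book = adaptive_max_pool(x, (3, 3))
    assert y.shape == (2, 3, 3, 3)
    for i in range(3):
        r0, r1 = (i * 7) // 3, -(-((i + 1) * 7) // 3)
        for j in range(3):
            c0, c1 = (j * 7) // 3, -(-((j + 1) * 7) // 3)
            assert np.allclose(y[:, i, j, :], x[:, r0:r1, c0:c1, :].max(axis=(1, 2)))
    same, book2 = adaptive_max_pool(x, (7, 7))
    assert book2 is None and np.array_equal(same, x)
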