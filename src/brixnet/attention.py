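"""Channel and spatial attention with cross-layer propagation.

Channel attention squeezes a feature map along its spatial axes (global
average and global max pooling), pushes both pooled vectors through a shared
two-layer perceptron, adds a learned projection of the *previous* layer's
attention weights (the cross-layer pathway), and squashes the weighted sum
through a sigmoid:

    M_c^l = sigma(l1 * MLP(avgpool(F)) + l2 * MLP(maxpool(F))
                  + l3 * MLP(W0(M_c^{l-1})))

Spatial attention pools along the channel axis instead, concatenates the two
maps with a convolved copy of the previous layer's attention map, and fuses
them with a single convolution:

    M_s^l = sigma(Ws[avgpool_c(F), maxpool_c(F), Wl(M_s^{l-1})])

The fusion coefficients l1..l3 are learnable scalars initialised at 1.0.  At
the first layer no previous attention exists and the cross-layer term is
dropped.  Both a pure-functional single-tensor API (used as an oracle surface)
and batched trainable layers are provided; they share the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .nn import BatchNorm, Conv2d, Dense, Param, ReLU, _im2col

__all__ = [
    "ChannelAttentionState",
    "SpatialAttentionState",
    "channel_pool",
    "spatial_pool",
    "channel_attention",
    "spatial_attention",
    "apply_channel_attention",
    "apply_spatial_attention",
    "SharedMLP",
    "ChannelAttentionLayer",
    "SpatialAttentionLayer",
    "adaptive_max_pool",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


# ---------------------------------------------------------------------------
# functional API (single tensor H x W x C); parameters live in state objects
# ---------------------------------------------------------------------------


@dataclass
class ChannelAttentionState:
    """Parameters of one channel-attention block (functional form).

    ``w1/b1/w2/b2`` form the shared perceptron C -> C/r -> C; ``w0/b0`` project
    the previous layer's weight vector onto the current channel count,
    followed by eval-mode batch normalisation (``bn_*``) and ReLU.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    w0: np.ndarray | None = None
    b0: np.ndarray | None = None
    bn_gamma: np.ndarray | None = None
    bn_beta: np.ndarray | None = None
    bn_mean: np.ndarray | None = None
    bn_var: np.ndarray | None = None

    @classmethod
    def zeros(cls, c: int, r: int = 8, c_prev: int | None = None) -> "ChannelAttentionState":
        h = max(c // r, 1)
        st = cls(
            w1=np.zeros((c, h)), b1=np.zeros(h), w2=np.zeros((h, c)), b2=np.zeros(c)
        )
        if c_prev is not None:
            st.w0 = np.zeros((c_prev, c))
            st.b0 = np.zeros(c)
            st.bn_gamma, st.bn_beta = np.ones(c), np.zeros(c)
            st.bn_mean, st.bn_var = np.zeros(c), np.ones(c)
        return st

    def mlp(self, v: np.ndarray) -> np.ndarray:
        return np.maximum(v @ self.w1 + self.b1, 0.0) @ self.w2 + self.b2

    def shallow_path(self, prev: np.ndarray) -> np.ndarray:
        z = prev @ self.w0 + self.b0
        z = self.bn_gamma * (z - self.bn_mean) / np.sqrt(self.bn_var + 1e-5) + self.bn_beta
        return self.mlp(np.maximum(z, 0.0))


@dataclass
class SpatialAttentionState:
    """Parameters of one spatial-attention block (functional form).

    ``ws`` fuses the concatenated [avg, max(, Wl(prev))] maps to one channel;
    ``wl`` is the 3x3 cross-layer transfer convolution on the previous map.
    """

    ws: np.ndarray  # (k, k, n_in, 1)
    bs: np.ndarray  # (1,)
    wl: np.ndarray | None = None  # (3, 3, 1, 1)
    bl: np.ndarray | None = None

    @classmethod
    def zeros(cls, first_layer: bool = True, kernel: int = 7) -> "SpatialAttentionState":
        n_in = 2 if first_layer else 3
        st = cls(ws=np.zeros((kernel, kernel, n_in, 1)), bs=np.zeros(1))
        if not first_layer:
            st.wl = np.zeros((3, 3, 1, 1))
            st.bl = np.zeros(1)
        return st


def channel_pool(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global average and global max over the spatial axes -> two C-vectors."""
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3 or f.shape[0] < 1 or f.shape[1] < 1:
        raise ValueError(f"expected a nonempty H x W x C tensor, got shape {f.shape}")
    return f.mean(axis=(0, 1)), f.max(axis=(0, 1))


def spatial_pool(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel average and max over the channel axis -> two H x W maps."""
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3 or f.shape[2] < 1:
        raise ValueError(f"expected a nonempty H x W x C tensor, got shape {f.shape}")
    return f.mean(axis=2), f.max(axis=2)


def channel_attention(
    f: np.ndarray, shallow_weights: np.ndarray | None, state: ChannelAttentionState
) -> np.ndarray:
    """Attention weight vector (strictly in (0,1)) for one feature tensor."""
    m_avg, m_max = channel_pool(f)
    s = state.lambda1 * state.mlp(m_avg) + state.lambda2 * state.mlp(m_max)
    if shallow_weights is not None:
        if state.w0 is None:
            raise ValueError("state has no shallow pathway (w0 is None)")
        shallow_weights = np.asarray(shallow_weights, dtype=np.float64)
        if shallow_weights.shape[0] != state.w0.shape[0]:
            raise ValueError("shallow weight length incompatible with W0")
        s = s + state.lambda3 * state.shallow_path(shallow_weights)
    return _sigmoid(s)


def apply_channel_attention(f: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Rescale each channel: out[h,w,c] = F[h,w,c] * weights[c]."""
    f = np.asarray(f, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (f.shape[2],):
        raise ValueError(f"weights length {weights.shape} != channel count {f.shape[2]}")
    return f * weights[None, None, :]


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'same' correlation of an H x W x Cin image with a (k,k,Cin,Cout) kernel."""
    k = w.shape[0]
    h, wdt, _ = x.shape
    cols = _im2col(x[None], k)
    return (cols @ w.reshape(-1, w.shape[3]) + b).reshape(h, wdt, w.shape[3])


def spatial_attention(
    f: np.ndarray, shallow_map: np.ndarray | None, state: SpatialAttentionState
) -> np.ndarray:
    """Attention map H x W (strictly in (0,1)) for one feature tensor."""
    p_avg, p_max = spatial_pool(f)
    h, w = p_avg.shape
    planes = [p_avg[..., None], p_max[..., None]]
    if shallow_map is not None:
        if state.wl is None:
            raise ValueError("state has no cross-layer pathway (wl is None)")
        shallow_map = np.asarray(shallow_map, dtype=np.float64)
        if shallow_map.shape != (h, w):
            shallow_map = adaptive_max_pool(shallow_map[None, ..., None], (h, w))[0][0, ..., 0]
        planes.append(_conv_same(shallow_map[..., None], state.wl, state.bl))
    cat = np.concatenate(planes, axis=2)
    if cat.shape[2] != state.ws.shape[2]:
        raise ValueError(
            f"fusion kernel expects {state.ws.shape[2]} planes, got {cat.shape[2]}"
        )
    return _sigmoid(_conv_same(cat, state.ws, state.bs)[..., 0])


def apply_spatial_attention(f: np.ndarray, attn_map: np.ndarray) -> np.ndarray:
    """Rescale each pixel: out[h,w,c] = F[h,w,c] * map[h,w]."""
    f = np.asarray(f, dtype=np.float64)
    attn_map = np.asarray(attn_map, dtype=np.float64)
    if attn_map.shape != f.shape[:2]:
        raise ValueError(f"map shape {attn_map.shape} != spatial dims {f.shape[:2]}")
    return f * attn_map[:, :, None]


def adaptive_max_pool(
    x: np.ndarray, out_hw: tuple[int, int]
) -> tuple[np.ndarray, list | None]:
    """Adaptive max pooling of (N,H,W,C) to (N,out_h,out_w,C).

    Output cell (i, j) pools the input window [floor(i*H/oh), ceil((i+1)*H/oh)).
    Returns the pooled array and per-cell argmax bookkeeping for backprop
    (None when the operation is the identity).
    """
    n, h, w, c = x.shape
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return x, None
    y = np.empty((n, oh, ow, c))
    book = []
    for i in range(oh):
        r0, r1 = (i * h) // oh, -(-((i + 1) * h) // oh)
        for j in range(ow):
            c0, c1 = (j * w) // ow, -(-((j + 1) * w) // ow)
            block = x[:, r0:r1, c0:c1, :].reshape(n, -1, c)
            arg = block.argmax(axis=1)
            y[:, i, j, :] = np.take_along_axis(block, arg[:, None, :], axis=1)[:, 0, :]
            book.append((i, j, r0, c0, c1 - c0, arg))
    return y, book


def _adaptive_max_unpool(dy: np.ndarray, xshape: tuple, book: list | None) -> np.ndarray:
    if book is None:
        return dy
    n, h, w, c = xshape
    dx = np.zeros(xshape)
    nn_ = np.arange(n)[:, None]
    ch = np.arange(c)[None, :]
    for i, j, r0, c0, bw, arg in book:
        rr = r0 + arg // bw
        cc = c0 + arg % bw
        np.add.at(dx, (nn_, rr, cc, ch), dy[:, i, j, :])
    return dx


# ---------------------------------------------------------------------------
# batched trainable layers
# ---------------------------------------------------------------------------


class SharedMLP:
    """Two dense layers with an internal ReLU, shared across pooled branches."""

    def __init__(self, c: int, r: int, rng: np.random.Generator, name: str = "camlp",
                 dtype=np.float64):
        hidden = max(c // r, 1)
        self.fc1 = Dense(c, hidden, rng, name=f"{name}.fc1", dtype=dtype)
        self.act = ReLU()
        self.fc2 = Dense(hidden, c, rng, name=f"{name}.fc2", dtype=dtype)

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(x, training), training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(dy)))


class ChannelAttentionLayer:
    """Batched channel attention with cross-layer weight fusion.

    ``forward`` maps (F (N,H,W,C), prev weights (N,C_prev) | None) to
    (F * w, w (N,C)); ``backward`` mirrors it.  With ``frozen=True`` the
    weights are fixed at exactly 1 and the block is a bitwise no-op.
    """

    def __init__(
        self,
        c: int,
        rng: np.random.Generator,
        c_prev: int | None = None,
        r: int = 8,
        name: str = "ca",
        dtype=np.float64,
    ):
        self.c, self.c_prev = c, c_prev
        self.mlp = SharedMLP(c, r, rng, name=name, dtype=dtype)
        self.lambda1 = Param(np.array(1.0), f"{name}.lambda1", dtype)
        self.lambda2 = Param(np.array(1.0), f"{name}.lambda2", dtype)
        if c_prev is not None:
            self.lambda3 = Param(np.array(1.0), f"{name}.lambda3", dtype)
            self.w0 = Dense(c_prev, c, rng, name=f"{name}.w0", dtype=dtype)
            self.w0_bn = BatchNorm(c, axes=(0,), name=f"{name}.w0bn", dtype=dtype)
            self.w0_act = ReLU()
        self.frozen = False
        self._ctx: list[tuple] = []

    def params(self) -> list[Param]:
        if self.frozen:
            return []
        out = self.mlp.params() + [self.lambda1, self.lambda2]
        if self.c_prev is not None:
            out += [self.lambda3] + self.w0.params() + self.w0_bn.params()
        return out

    def forward(
        self, f: np.ndarray, prev: np.ndarray | None, training: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        n, h, w, c = f.shape
        if self.frozen:
            if training:
                self._ctx.append(None)
            return f, np.ones((n, c))
        m_avg = f.mean(axis=(1, 2))
        flat = f.reshape(n, h * w, c)
        arg = flat.argmax(axis=1)
        m_max = np.take_along_axis(flat, arg[:, None, :], axis=1)[:, 0, :]
        a = self.mlp.forward(m_avg, training)
        b = self.mlp.forward(m_max, training)
        s = self.lambda1.value * a + self.lambda2.value * b
        z = None
        if prev is not None:
            if self.c_prev is None:
                raise ValueError("layer has no cross-layer pathway but prev weights given")
            hvec = self.w0_act.forward(
                self.w0_bn.forward(self.w0.forward(prev, training), training), training
            )
            z = self.mlp.forward(hvec, training)
            s = s + self.lambda3.value * z
        wgt = _sigmoid(s)
        if training:
            self._ctx.append((f, arg, a, b, z, wgt))
        return f * wgt[:, None, None, :], wgt

    def backward(
        self, dout: np.ndarray, dw_next: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        ctx = self._ctx.pop()
        if ctx is None:
            return dout, None
        f, arg, a, b, z, wgt = ctx
        n, h, w, c = f.shape
        dwgt = (dout * f).sum(axis=(1, 2))
        if dw_next is not None:
            dwgt = dwgt + dw_next
        df = dout * wgt[:, None, None, :]
        ds = dwgt * wgt * (1.0 - wgt)
        self.lambda1.grad += (ds * a).sum()
        self.lambda2.grad += (ds * b).sum()
        dprev = None
        if z is not None:
            self.lambda3.grad += (ds * z).sum()
            dh = self.mlp.backward(self.lambda3.value * ds)
            dprev = self.w0.backward(self.w0_bn.backward(self.w0_act.backward(dh)))
        db_ = self.mlp.backward(self.lambda2.value * ds)
        da = self.mlp.backward(self.lambda1.value * ds)
        df = df + da[:, None, None, :] / (h * w)
        dmax = np.zeros((n, h * w, c))
        np.put_along_axis(dmax, arg[:, None, :], db_[:, None, :], axis=1)
        df = df + dmax.reshape(n, h, w, c)
        return df, dprev

    def export_state(self) -> ChannelAttentionState:
        st = ChannelAttentionState(
            w1=self.mlp.fc1.W.value.copy(),
            b1=self.mlp.fc1.b.value.copy(),
            w2=self.mlp.fc2.W.value.copy(),
            b2=self.mlp.fc2.b.value.copy(),
            lambda1=float(self.lambda1.value),
            lambda2=float(self.lambda2.value),
        )
        if self.c_prev is not None:
            st.lambda3 = float(self.lambda3.value)
            st.w0 = self.w0.W.value.copy()
            st.b0 = self.w0.b.value.copy()
            st.bn_gamma = self.w0_bn.gamma.value.copy()
            st.bn_beta = self.w0_bn.beta.value.copy()
            st.bn_mean = self.w0_bn.running_mean.copy()
            st.bn_var = self.w0_bn.running_var.copy()
        return st


class SpatialAttentionLayer:
    """Batched spatial attention with cross-layer map fusion (7x7 fusion conv)."""

    def __init__(
        self, rng: np.random.Generator, first_layer: bool, kernel: int = 7, name: str = "sa",
        dtype=np.float64,
    ):
        self.first_layer = first_layer
        n_in = 2 if first_layer else 3
        self.ws = Conv2d(n_in, 1, kernel, rng, name=f"{name}.ws", dtype=dtype)
        if not first_layer:
            self.wl = Conv2d(1, 1, 3, rng, name=f"{name}.wl", dtype=dtype)
        self.frozen = False
        self._ctx: list[tuple] = []

    def params(self) -> list[Param]:
        if self.frozen:
            return []
        out = self.ws.params()
        if not self.first_layer:
            out += self.wl.params()
        return out

    def forward(
        self, f: np.ndarray, prev: np.ndarray | None, training: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        n, h, w, c = f.shape
        if self.frozen:
            if training:
                self._ctx.append(None)
            return f, np.ones((n, h, w))
        p_avg = f.mean(axis=3)
        arg = f.argmax(axis=3)
        p_max = np.take_along_axis(f, arg[..., None], axis=3)[..., 0]
        planes = [p_avg[..., None], p_max[..., None]]
        book = prev_shape = None
        if prev is not None:
            if self.first_layer:
                raise ValueError("first spatial layer has no cross-layer pathway")
            prev_shape = prev.shape
            pooled, book = adaptive_max_pool(prev[..., None], (h, w))
            planes.append(self.wl.forward(pooled, training))
        cat = np.concatenate(planes, axis=3)
        m = _sigmoid(self.ws.forward(cat, training)[..., 0])
        if training:
            self._ctx.append((f, arg, m, book, prev_shape))
        return f * m[..., None], m

    def backward(
        self, dout: np.ndarray, dm_next: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        ctx = self._ctx.pop()
        if ctx is None:
            return dout, None
        f, arg, m, book, prev_shape = ctx
        n, h, w, c = f.shape
        dm = (dout * f).sum(axis=3)
        if dm_next is not None:
            dm = dm + dm_next
        df = dout * m[..., None]
        dz = (dm * m * (1.0 - m))[..., None]
        dcat = self.ws.backward(dz)
        df = df + dcat[..., 0:1] / c
        dmax = np.zeros_like(f)
        np.put_along_axis(dmax, arg[..., None], dcat[..., 1:2], axis=3)
        df = df + dmax
        dprev = None
        if dcat.shape[3] == 3:
            dpooled = self.wl.backward(dcat[..., 2:3])
            dprev = _adaptive_max_unpool(dpooled, (n, *prev_shape[1:], 1), book)[..., 0]
        return df, dprev

    def export_state(self) -> SpatialAttentionState:
        st = SpatialAttentionState(ws=self.ws.W.value.copy(), bs=self.ws.b.value.copy())
        if not self.first_layer:
            st.wl = self.wl.W.value.copy()
            st.bl = self.wl.b.value.copy()
        return st
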