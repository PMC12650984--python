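"""Minimal NumPy neural-network core with reverse-mode gradients.

Layers follow the NHWC layout (batch, height, width, channels) and cache their
forward context on a stack, so a module shared across several call sites (the
shared perceptron inside channel attention) accumulates correct gradients when
``backward`` is invoked in reverse call order.  Contexts are cached only for
``training=True`` forwards — inference passes allocate nothing — so
``backward`` is valid only after a training-mode forward.  Gradient
correctness of every layer is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Dense",
    "BatchNorm",
    "ReLU",
    "ELU",
    "Sigmoid",
    "Softmax",
    "Identity",
    "MaxPool2d",
    "GlobalAvgPool",
    "make_activation",
    "make_optimizer",
    "SGD",
    "Adam",
    "RMSProp",
    "AdaBound",
]


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "", dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-pad to 'same' and unfold k x k windows -> (N*H*W, k*k*C)."""
    p = k // 2
    xp = np.pad(x, [(0, 0), (p, p), (p, p), (0, 0)])
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    n, h, w, c = x.shape
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * c)


class Conv2d(Layer):
    """Stride-1 'same'-padded 2-D convolution (cross-correlation), odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", dtype=np.float64):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        self.dtype = dtype
        std = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.W = Param(rng.normal(0.0, std, (kernel, kernel, c_in, c_out)), f"{name}.W", dtype)
        self.b = Param(np.zeros(c_out), f"{name}.b", dtype)
        self._ctx: list[tuple] = []

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        n, h, w, _ = x.shape
        cols = _im2col(x, self.k)
        y = cols @ self.W.value.reshape(-1, self.c_out) + self.b.value
        if training:
            self._ctx.append((cols, x.shape))
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._ctx.pop()
        n, h, w, _ = xshape
        dyr = np.asarray(dy, dtype=self.dtype).reshape(-1, self.c_out)
        self.W.grad += (cols.T @ dyr).reshape(self.W.value.shape)
        self.b.grad += dyr.sum(axis=0)
        # dx = 'same' correlation of dy with the spatially flipped, transposed kernel
        wf = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.c_in)
        dx = _im2col(np.asarray(dy, dtype=self.dtype), self.k) @ wf
        return dx.reshape(n, h, w, self.c_in)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "fc", dtype=np.float64):
        std = np.sqrt(2.0 / n_in)
        self.dtype = dtype
        self.W = Param(rng.normal(0.0, std, (n_in, n_out)), f"{name}.W", dtype)
        self.b = Param(np.zeros(n_out), f"{name}.b", dtype)
        self._ctx: list[np.ndarray] = []

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if training:
            self._ctx.append(x)
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._ctx.pop()
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalisation over the given axes (``(0,1,2)`` for NHWC, ``(0,)`` for vectors)."""

    def __init__(self, c: int, axes: tuple[int, ...] = (0, 1, 2), momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "bn", dtype=np.float64):
        self.axes = axes
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(c), f"{name}.gamma", dtype)
        self.beta = Param(np.zeros(c), f"{name}.beta", dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._seen_batch = False
        self._collect: list | None = None
        self._ctx: list[tuple] = []

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            if self._collect is not None:
                self._collect[0] += 1
                self._collect[1] = self._collect[1] + mu
                self._collect[2] = self._collect[2] + var
            elif not self._seen_batch:
                # seed the EMA with the first batch so eval mode is usable
                # even after short training runs
                self.running_mean, self.running_var = mu.copy(), var.copy()
                self._seen_batch = True
            else:
                self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
                self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        if training:
            self._ctx.append((xhat, invstd, x.shape))
        return self.gamma.value * xhat + self.beta.value

    def start_stat_collection(self) -> None:
        """Begin averaging batch statistics over subsequent training forwards."""
        self._collect = [0, 0.0, 0.0]

    def finish_stat_collection(self) -> None:
        """Replace the EMA running stats by the collected full-data averages."""
        k, msum, vsum = self._collect
        if k > 0:
            self.running_mean = msum / k
            self.running_var = vsum / k
            self._seen_batch = True
        self._collect = None

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, xshape = self._ctx.pop()
        m = np.prod([xshape[a] for a in self.axes])
        self.gamma.grad += (dy * xhat).sum(axis=self.axes)
        self.beta.grad += dy.sum(axis=self.axes)
        dxhat = dy * self.gamma.value
        dx = (invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=self.axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=self.axes, keepdims=True)
        )
        return dx


class ReLU(Layer):
    def __init__(self):
        self._ctx: list[np.ndarray] = []

    def forward(self, x, training=False):
        if training:
            self._ctx.append(x > 0)
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._ctx.pop()


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._ctx: list[np.ndarray] = []

    def forward(self, x, training=False):
        y = np.where(x > 0, x, self.alpha * (np.exp(np.minimum(x, 0)) - 1.0))
        if training:
            self._ctx.append((x > 0, y))
        return y

    def backward(self, dy):
        pos, y = self._ctx.pop()
        return dy * np.where(pos, 1.0, y + self.alpha)


class Sigmoid(Layer):
    def __init__(self):
        self._ctx: list[np.ndarray] = []

    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._ctx.append(y)
        return y

    def backward(self, dy):
        y = self._ctx.pop()
        return dy * y * (1.0 - y)


class Softmax(Layer):
    """Softmax over the trailing (channel/feature) axis."""

    def __init__(self):
        self._ctx: list[np.ndarray] = []

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        if training:
            self._ctx.append(y)
        return y

    def backward(self, dy):
        y = self._ctx.pop()
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class Identity(Layer):
    def forward(self, x, training=False):
        return x

    def backward(self, dy):
        return dy


class MaxPool2d(Layer):
    """Max pooling; passes through unchanged when the map is smaller than the window."""

    def __init__(self, pool: int, stride: int):
        self.pool, self.stride = pool, stride
        self._ctx: list[tuple] = []

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if h < self.pool or w < self.pool:
            if training:
                self._ctx.append(None)
            return x
        p, s = self.pool, self.stride
        win = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::s, ::s]  # (N,Ho,Wo,C,p,p)
        n_, ho, wo, c_, _, _ = win.shape
        flat = win.reshape(n_, ho, wo, c_, p * p)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        rr = (np.arange(ho) * s)[None, :, None, None] + arg // p
        cc = (np.arange(wo) * s)[None, None, :, None] + arg % p
        nn_ = np.arange(n)[:, None, None, None]
        ch = np.arange(c)[None, None, None, :]
        flat_idx = ((nn_ * h + rr) * w + cc) * c + ch
        if training:
            self._ctx.append((x.shape, flat_idx))
        return y

    def backward(self, dy):
        ctx = self._ctx.pop()
        if ctx is None:
            return dy
        xshape, flat_idx = ctx
        dx = np.zeros(int(np.prod(xshape)))
        np.add.at(dx, flat_idx.ravel(), dy.ravel())
        return dx.reshape(xshape)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._ctx: list[tuple] = []

    def forward(self, x, training=False):
        if training:
            self._ctx.append(x.shape)
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._ctx.pop()
        return np.broadcast_to(dy[:, None, None, :] / (h * w), (n, h, w, c)).copy()


def make_activation(name: str) -> Layer:
    table = {"relu": ReLU, "elu": ELU, "sigmoid": Sigmoid, "softmax": Softmax, "linear": Identity}
    key = name.lower()
    if key not in table:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(table)}")
    return table[key]()


class Optimizer:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class RMSProp(Optimizer):
    def __init__(self, params, lr, rho=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


class AdaBound(Optimizer):
    """Adam with step sizes clipped toward an SGD-like final learning rate."""

    def __init__(self, params, lr, final_lr=0.1, gamma=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.final_lr, self.gamma = final_lr, gamma
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        lower = self.final_lr * (1.0 - 1.0 / (self.gamma * self.t + 1.0))
        upper = self.final_lr * (1.0 + 1.0 / (self.gamma * self.t))
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            eta = np.clip(self.lr / (np.sqrt(v / b2c) + self.eps), lower, upper)
            p.value -= eta * (m / b1c)


def make_optimizer(name: str, params: list[Param], lr: float) -> Optimizer:
    table = {"sgd": SGD, "adam": Adam, "adabound": AdaBound, "rmsprop": RMSProp}
    key = name.lower()
    if key not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[key](params, lr)
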