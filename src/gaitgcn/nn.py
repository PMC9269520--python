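"""Minimal numpy neural-network layers with manual backpropagation.

Everything the gait network needs — spatial graph convolution, (separable)
temporal convolution, batch normalization, spatiotemporal joint attention,
global average pooling, a linear classifier, softmax cross-entropy and
SGD/Adam optimizers — implemented on plain numpy arrays.

Feature maps are held internally in (N, T, V, C) layout: batch, frames,
joints, channels.  That keeps the hot operations (channel mixing, joint
aggregation, temporal windowing) as contiguous BLAS matmuls.  The public
model API converts from the conventional channel-first (C, T, V) view at
the boundary.

Every layer implements ``forward(x)`` (caching what backward needs) and
``backward(gy)`` (returning the input gradient and accumulating parameter
gradients).  Layers are deterministic given the seeded initializer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "BatchNorm",
    "InputBatchNorm",
    "ReLU",
    "SpatialGraphConv",
    "TemporalConv",
    "STJointAttention",
    "GlobalAveragePool",
    "Linear",
    "softmax",
    "cross_entropy",
    "SGD",
    "Adam",
]

DTYPE = np.float32


_ONES_CACHE: dict[int, np.ndarray] = {}


def _ones(m: int) -> np.ndarray:
    out = _ONES_CACHE.get(m)
    if out is None:
        out = np.ones(m, dtype=DTYPE)
        _ONES_CACHE[m] = out
    return out


def colsum(x2d: np.ndarray) -> np.ndarray:
    """Column sums of a 2D array through BLAS (fast path for axis-0 sums)."""
    return _ones(x2d.shape[0]) @ x2d


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base layer: parameter bookkeeping and train/eval mode."""

    def __init__(self) -> None:
        self._params: list[Param] = []
        self._children: list[Layer] = []
        self.training = True

    def add_param(self, name: str, data: np.ndarray) -> Param:
        p = Param(f"{type(self).__name__}.{name}", data)
        self._params.append(p)
        return p

    def add_child(self, child: "Layer") -> "Layer":
        self._children.append(child)
        return child

    def parameters(self) -> list[Param]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for c in self._children:
            c.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, T, V) of an NTVC map."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param("gamma", np.ones(channels))
        self.beta = self.add_param("beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._axes = (0, 1, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        shape = x.shape
        C = shape[-1]
        xr = x.reshape(-1, C)
        if self.training:
            m = xr.shape[0]
            mu = colsum(xr) / m
            xc = xr - mu
            var = np.einsum("mc,mc->c", xc, xc) / m
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
            xc = xr - mu
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xc *= self._inv_std
        self._xhat = xc
        y = xc * self.gamma.data
        y += self.beta.data
        return y.reshape(shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        shape = gy.shape
        C = shape[-1]
        gyr = gy.reshape(-1, C)
        m = gyr.shape[0]
        self.gamma.grad += np.einsum("mc,mc->c", gyr, self._xhat)
        self.beta.grad += colsum(gyr)
        if not self.training:
            return (gyr * (self.gamma.data * self._inv_std)).reshape(shape)
        g = gyr * self.gamma.data
        mean_g = colsum(g) / m
        mean_gx = np.einsum("mc,mc->c", g, self._xhat) / m
        g -= mean_g
        g -= self._xhat * mean_gx
        g *= self._inv_std
        return g.reshape(shape)


class InputBatchNorm(BatchNorm):
    """Batch normalization over the flattened joint·channel axis.

    Applied to the raw branch input: each (joint, channel) pair is
    normalized independently over the batch and frame axes, so scale
    differences between e.g. absolute positions and angles are removed
    before the first graph convolution.
    """

    def __init__(self, joints: int, channels: int, **kw):
        super().__init__(joints * channels, **kw)
        self.joints = joints
        self.channels = channels
        self._axes = (0, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, V, C = x.shape
        y = super().forward(x.reshape(N, T, V * C))
        return y.reshape(N, T, V, C)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, T, V, C = gy.shape
        gx = super().backward(gy.reshape(N, T, V * C))
        return gx.reshape(N, T, V, C)


class SpatialGraphConv(Layer):
    """Partitioned graph convolution over the joint axis.

    out = Σ_k A_k · (X W_k) + b, applied independently per frame, where
    A_k is the k-th normalized partition matrix (entry (i, j) weights
    the contribution of source joint j to target joint i).
    """

    def __init__(self, in_channels: int, out_channels: int,
                 adjacency: np.ndarray, rng: np.random.Generator,
                 edge_importance: bool = False):
        super().__init__()
        A = np.asarray(adjacency, dtype=DTYPE)
        if A.ndim == 2:
            A = A[None]
        self.A = A  # K×V×V, fixed
        K = A.shape[0]
        # optional learnable edge-importance mask on the adjacency support
        self.mask = (
            self.add_param("mask", np.ones_like(A)) if edge_importance
            else None
        )
        scale = np.sqrt(2.0 / (in_channels * K))
        self.W = self.add_param(
            "W", rng.normal(0.0, scale, size=(K, in_channels, out_channels))
        )
        self.b = self.add_param("b", np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels

    def _effective_A(self) -> np.ndarray:
        if self.mask is None:
            return self.A
        return self.A * self.mask.data

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, V, C = x.shape
        K = self.A.shape[0]
        Co = self.out_channels
        self._x = x
        xr = x.reshape(-1, C)
        # one matmul for all partitions: (·, C) @ (C, K·Co)
        z = xr @ self.W.data.transpose(1, 0, 2).reshape(C, K * Co)
        self._z = z.reshape(N * T, V, K, Co)
        A = self._effective_A()
        out = np.matmul(A[0], self._z[:, :, 0])
        for k in range(1, K):
            out += np.matmul(A[k], self._z[:, :, k])
        out += self.b.data
        return out.reshape(N, T, V, Co)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, T, V, Co = gy.shape
        K = self.A.shape[0]
        C = self.in_channels
        gyr = gy.reshape(N * T, V, Co)
        self.b.grad += colsum(gy.reshape(-1, Co))
        A = self._effective_A()
        gz = np.empty((N * T, V, K, Co), dtype=DTYPE)
        for k in range(K):
            gz[:, :, k] = np.matmul(A[k].T, gyr)
            if self.mask is not None:
                gA = np.einsum("bwo,bvo->wv", gyr, self._z[:, :, k])
                self.mask.grad[k] += gA * self.A[k]
        xr = self._x.reshape(-1, C)
        gzr = gz.reshape(-1, K * Co)
        self.W.grad += (xr.T @ gzr).reshape(C, K, Co).transpose(1, 0, 2)
        gx = gzr @ self.W.data.transpose(1, 0, 2).reshape(C, K * Co).T
        return gx.reshape(N, T, V, C)


class TemporalConv(Layer):
    """Convolution along the frame axis (kernel k × 1 over T × V).

    Symmetric zero padding of (k−1)/2 frames; output length
    T' = floor((T + 2p − k)/stride) + 1 = ceil(T/stride).  With
    ``separable=True`` the layer factorizes into a depth-wise filter per
    channel followed by a 1×1 point-wise channel mix, cutting the weight
    count from k·C_in·C_out to k·C_in + C_in·C_out.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, separable: bool, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"temporal kernel must be odd, got {kernel}")
        self.kernel = kernel
        self.stride = stride
        self.separable = separable
        self.in_channels = in_channels
        self.out_channels = out_channels
        if separable:
            self.Wd = self.add_param(
                "Wd",
                rng.normal(0.0, np.sqrt(2.0 / kernel),
                           size=(kernel, in_channels)),
            )
            self.Wp = self.add_param(
                "Wp",
                rng.normal(0.0, np.sqrt(2.0 / in_channels),
                           size=(in_channels, out_channels)),
            )
        else:
            self.W = self.add_param(
                "W",
                rng.normal(0.0, np.sqrt(2.0 / (kernel * in_channels)),
                           size=(kernel, in_channels, out_channels)),
            )
        self.b = self.add_param("b", np.zeros(out_channels))

    def _pad(self, x: np.ndarray, pad: int) -> np.ndarray:
        if pad == 0:
            return x
        N, T, V, C = x.shape
        xp = np.zeros((N, T + 2 * pad, V, C), dtype=DTYPE)
        xp[:, pad : pad + T] = x
        return xp

    @staticmethod
    def _windows(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
        """Strided view (N, To, V, C, k) over the padded frame axis."""
        win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
        return win[:, ::stride]

    def _t_out(self, T: int) -> int:
        p = (self.kernel - 1) // 2
        return (T + 2 * p - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, V, C = x.shape
        p = (self.kernel - 1) // 2
        xp = self._pad(x, p)
        self._T = T
        self._xp = xp
        win = self._windows(xp, self.kernel, self.stride)
        if self.separable:
            yd = np.einsum("ntvck,kc->ntvc", win, self.Wd.data)
            self._yd = yd
            y = yd.reshape(-1, C) @ self.Wp.data
            y += self.b.data
            return y.reshape(N, yd.shape[1], V, -1)
        y = np.einsum("ntvck,kco->ntvo", win, self.W.data)
        y += self.b.data
        return y

    def _upsample_grad(self, g: np.ndarray) -> np.ndarray:
        """Insert stride-1 zeros between frames of the output gradient."""
        if self.stride == 1:
            return g
        N, To, V, C = g.shape
        L = (To - 1) * self.stride + 1
        up = np.zeros((N, L, V, C), dtype=DTYPE)
        up[:, :: self.stride] = g
        return up

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, To, V, Co = gy.shape
        p = (self.kernel - 1) // 2
        self.b.grad += colsum(gy.reshape(-1, Co))
        win_x = self._windows(self._xp, self.kernel, self.stride)
        if self.separable:
            gyr = gy.reshape(-1, Co)
            self.Wp.grad += self._yd.reshape(-1, self.in_channels).T @ gyr
            gyd = (gyr @ self.Wp.data.T).reshape(
                N, To, V, self.in_channels
            )
            self.Wd.grad += np.einsum("ntvck,ntvc->kc", win_x, gyd)
            # input gradient = correlation of the (upsampled) output
            # gradient with the flipped kernel
            gup = self._pad(self._upsample_grad(gyd), self.kernel - 1)
            win_g = self._windows(gup, self.kernel, 1)
            gxp = np.einsum(
                "ntvck,kc->ntvc", win_g, self.Wd.data[::-1]
            )
        else:
            self.W.grad += np.einsum("ntvck,ntvo->kco", win_x, gy)
            gup = self._pad(self._upsample_grad(gy), self.kernel - 1)
            win_g = self._windows(gup, self.kernel, 1)
            gxp = np.einsum(
                "ntvok,koc->ntvc", win_g,
                self.W.data[::-1].transpose(0, 2, 1),
            )
        # frames past the last window start receive no gradient
        deficit = (self._T + 2 * p) - gxp.shape[1]
        if deficit:
            gxp = self._pad_end(gxp, deficit)
        return gxp[:, p : p + self._T] if p else gxp

    @staticmethod
    def _pad_end(g: np.ndarray, deficit: int) -> np.ndarray:
        N, L, V, C = g.shape
        out = np.zeros((N, L + deficit, V, C), dtype=DTYPE)
        out[:, :L] = g
        return out

    def weight_count(self, separable: bool | None = None) -> int:
        """Weight-array size (biases excluded) for this layer's geometry."""
        sep = self.separable if separable is None else separable
        if sep:
            return (self.kernel * self.in_channels
                    + self.in_channels * self.out_channels)
        return self.kernel * self.in_channels * self.out_channels


class STJointAttention(Layer):
    """Spatiotemporal joint attention.

    The input map is mean-pooled over joints (→ C×T) and over frames
    (→ C×V); the two pooled maps are concatenated along the pooled axis,
    compacted to C/r channels by a shared linear map, and expanded back
    to C by two independent linear maps — one for the frame axis, one
    for the joint axis.  Sigmoid squashing yields frame scores s_t and
    joint scores s_v whose channel-wise outer product gates the input:
    out[c,t,v] = x[c,t,v] · s_t[c,t] · s_v[c,v].

    ``identity_mode`` forces both score sets to 1 (ablation hook).
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"attention reduction {reduction} does not divide "
                f"channel width {channels}"
            )
        d = channels // reduction
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / d)
        self.W1 = self.add_param("W1", rng.normal(0.0, s1, size=(channels, d)))
        self.b1 = self.add_param("b1", np.zeros(d))
        self.Wt = self.add_param("Wt", rng.normal(0.0, s2, size=(d, channels)))
        self.bt = self.add_param("bt", np.zeros(channels))
        self.Wv = self.add_param("Wv", rng.normal(0.0, s2, size=(d, channels)))
        self.bv = self.add_param("bv", np.zeros(channels))
        self.channels = channels
        self.identity_mode = False
        self.last_scores: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, V, C = x.shape
        if self.identity_mode:
            ones_t = np.ones((N, T, C), dtype=DTYPE)
            ones_v = np.ones((N, V, C), dtype=DTYPE)
            self.last_scores = (ones_t, ones_v)
            return x
        self._x = x
        pt = x.mean(axis=2)               # N×T×C
        pv = x.mean(axis=1)               # N×V×C
        u = np.concatenate([pt, pv], axis=1)          # N×(T+V)×C
        hpre = u.reshape(-1, C) @ self.W1.data + self.b1.data
        h = np.where(hpre > 0, hpre, 0.0)
        self._u, self._hpre, self._h = u, hpre, h
        d = h.shape[-1]
        hr = h.reshape(N, T + V, d)
        st = hr[:, :T].reshape(-1, d) @ self.Wt.data + self.bt.data
        sv = hr[:, T:].reshape(-1, d) @ self.Wv.data + self.bv.data
        fs = sigmoid(st).reshape(N, T, C)
        js = sigmoid(sv).reshape(N, V, C)
        self._fs, self._js = fs, js
        self.last_scores = (fs, js)
        return x * fs[:, :, None, :] * js[:, None, :, :]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.identity_mode:
            return gy
        x, fs, js = self._x, self._fs, self._js
        N, T, V, C = x.shape
        gx = gy * fs[:, :, None, :] * js[:, None, :, :]
        g_fs = (gy * x * js[:, None, :, :]).sum(axis=2)
        g_js = (gy * x * fs[:, :, None, :]).sum(axis=1)
        g_st = (g_fs * fs * (1.0 - fs)).reshape(-1, C)
        g_sv = (g_js * js * (1.0 - js)).reshape(-1, C)
        d = self._h.shape[-1]
        hr = self._h.reshape(N, T + V, d)
        self.Wt.grad += hr[:, :T].reshape(-1, d).T @ g_st
        self.bt.grad += g_st.sum(axis=0)
        self.Wv.grad += hr[:, T:].reshape(-1, d).T @ g_sv
        self.bv.grad += g_sv.sum(axis=0)
        g_h = np.empty((N, T + V, d), dtype=DTYPE)
        g_h[:, :T] = (g_st @ self.Wt.data.T).reshape(N, T, d)
        g_h[:, T:] = (g_sv @ self.Wv.data.T).reshape(N, V, d)
        g_hpre = np.where(self._hpre > 0, g_h.reshape(-1, d), 0.0)
        self.W1.grad += self._u.reshape(-1, C).T @ g_hpre
        self.b1.grad += g_hpre.sum(axis=0)
        g_u = (g_hpre @ self.W1.data.T).reshape(N, T + V, C)
        gx += g_u[:, :T][:, :, None, :] / V
        gx += g_u[:, T:][:, None, :, :] / T
        return gx


class GlobalAveragePool(Layer):
    """Mean over frames and joints: NTVC → NC."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, T, V, C = self._shape
        return np.broadcast_to(
            gy[:, None, None, :] / (T * V), self._shape
        ).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / in_features)
        self.W = self.add_param(
            "W", rng.normal(0.0, scale, size=(in_features, out_features))
        )
        self.b = self.add_param("b", np.zeros(out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.data.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    N = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(p[np.arange(N), labels] + 1e-12).mean())
    g = p
    g[np.arange(N), labels] -= 1.0
    return loss, (g / N).astype(DTYPE)


class SGD:
    """Momentum SGD with optional step decay."""

    def __init__(self, params: list[Param], lr: float = 0.1,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
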