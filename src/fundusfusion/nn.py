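"""Minimal NumPy neural-network core.

Layers (2-D convolution, batch normalization, ReLU, max pooling, dense,
sigmoid) with hand-written forward/backward passes, a ``Sequential``
container, and an Adam optimizer.  Sized for the small tensors of this
classifier (inputs 3x78x116, 32 channels); convolutions use an
im2col/col2im formulation so each pass is a single GEMM.

Array layout is NCHW.  All layers are deterministic given the seeded
initializer; batch normalization keeps running statistics so evaluation
is deterministic for fixed weights.
"""

from __future__ import annotations

import copy

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Extract sliding windows as a (n*ho*wo, c*kh*kw) matrix."""
    n, c, h, w = x.shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw, :, :]  # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Scatter-add window gradients back onto the input grid."""
    n, c, h, w = xshape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    dwin = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros(xshape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw] += dwin[:, :, :, :, i, j]
    return dx


class Layer:
    """Base class; stateless layers need only forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution (cross-correlation), He-uniform initialized."""

    def __init__(self, in_ch, out_ch, kernel, stride=(1, 1), padding=(0, 0), rng=None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.ph, self.pw = padding
        rng = rng or np.random.default_rng()
        fan_in = in_ch * self.kh * self.kw
        bound = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(-bound, bound, size=(out_ch, in_ch, self.kh, self.kw))
        self.params["b"] = np.zeros(out_ch)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return (
            (h + 2 * self.ph - self.kh) // self.sh + 1,
            (w + 2 * self.pw - self.kw) // self.sw + 1,
        )

    def forward(self, x, train):
        if self.ph or self.pw:
            x = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        self._xshape = x.shape
        cols, ho, wo = _im2col(x, self.kh, self.kw, self.sh, self.sw)
        self._cols = cols
        Wm = self.params["W"].reshape(self.out_ch, -1)
        y = cols @ Wm.T + self.params["b"]
        n = x.shape[0]
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gout):
        n, oc, ho, wo = gout.shape
        g = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, oc)
        Wm = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] = (g.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = g.sum(axis=0)
        dcols = g @ Wm
        dx = _col2im(dcols, self._xshape, self.kh, self.kw, self.sh, self.sw)
        if self.ph or self.pw:
            dx = dx[:, :, self.ph : dx.shape[2] - self.ph, self.pw : dx.shape[3] - self.pw]
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.n_ch, self.momentum, self.eps = n_ch, momentum, eps
        self.params["gamma"] = np.ones(n_ch)
        self.params["beta"] = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x, train):
        if train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        m, v = mean[None, :, None, None], var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._train = train
        return self.params["gamma"][None, :, None, None] * self._xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, gout):
        axes = (0, 2, 3)
        self.grads["gamma"] = (gout * self._xhat).sum(axis=axes)
        self.grads["beta"] = gout.sum(axis=axes)
        gxhat = gout * self.params["gamma"][None, :, None, None]
        if not self._train:
            return gxhat / self._std[None, :, None, None]
        nelem = gout.shape[0] * gout.shape[2] * gout.shape[3]
        # standard batch-norm backward over the (batch, spatial) axes
        term = (
            gxhat
            - gxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (gxhat * self._xhat).sum(axis=axes, keepdims=True) / nelem
        )
        return term / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class MaxPool2D(Layer):
    """Max pooling with arbitrary kernel/stride (floor mode)."""

    def __init__(self, kernel, stride):
        super().__init__()
        self.kh, self.kw = kernel
        self.sh, self.sw = stride

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h - self.kh) // self.sh + 1, (w - self.kw) // self.sw + 1)

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._xshape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, :: self.sh, :: self.sw, :, :]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, self.kh * self.kw)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, gout):
        n, c, ho, wo = gout.shape
        dx = np.zeros(self._xshape, dtype=gout.dtype)
        di, dj = np.unravel_index(self._argmax, (self.kh, self.kw))
        rows = np.arange(ho)[None, None, :, None] * self.sh + di
        cols = np.arange(wo)[None, None, None, :] * self.sw + dj
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dx, (ni, ci, rows, cols), gout)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, He-uniform initialized."""

    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(6.0 / n_in)
        self.params["W"] = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class Sequential:
    """Chain of layers with shared forward/backward bookkeeping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


class FusionNetwork:
    """CNN and/or ANN branch feeding a dense head that emits p_hat.

    With both branches present the head consumes the concatenation of
    the CNN's feature vector and the ANN's final hidden representation;
    with a single branch it consumes that branch's output alone, which
    gives the standalone image-only and thickness-only models.
    """

    def __init__(self, cnn: Sequential | None, ann: Sequential | None, head: Sequential):
        if cnn is None and ann is None:
            raise ValueError("at least one branch is required")
        self.cnn, self.ann, self.head = cnn, ann, head

    def forward(self, images: np.ndarray | None, feats: np.ndarray | None, train: bool = False):
        parts = []
        if self.cnn is not None:
            if images is None:
                raise ValueError("this model requires image input")
            parts.append(self.cnn.forward(images, train))
        if self.ann is not None:
            if feats is None:
                raise ValueError("this model requires thickness-feature input")
            parts.append(self.ann.forward(feats, train))
        self._widths = [p.shape[1] for p in parts]
        z = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)
        return self.head.forward(z, train)[:, 0]

    def backward(self, gp: np.ndarray):
        gz = self.head.backward(gp[:, None])
        offset = 0
        chunks = []
        for wdt in self._widths:
            chunks.append(gz[:, offset : offset + wdt])
            offset += wdt
        it = iter(chunks)
        if self.cnn is not None:
            self.cnn.backward(next(it))
        if self.ann is not None:
            self.ann.backward(next(it))

    def parameters(self):
        for branch in (self.cnn, self.ann, self.head):
            if branch is not None:
                yield from branch.parameters()

    def get_state(self) -> list:
        """Deep copy of all parameters and batch-norm running stats."""
        state = []
        for branch in (self.cnn, self.ann, self.head):
            if branch is None:
                continue
            for layer in branch.layers:
                entry = {k: v.copy() for k, v in layer.params.items()}
                if isinstance(layer, BatchNorm2D):
                    entry["_running_mean"] = layer.running_mean.copy()
                    entry["_running_var"] = layer.running_var.copy()
                state.append(entry)
        return copy.deepcopy(state)

    def set_state(self, state: list) -> None:
        i = 0
        for branch in (self.cnn, self.ann, self.head):
            if branch is None:
                continue
            for layer in branch.layers:
                entry = state[i]
                for k in layer.params:
                    layer.params[k] = entry[k].copy()
                if isinstance(layer, BatchNorm2D):
                    layer.running_mean = entry["_running_mean"].copy()
                    layer.running_var = entry["_running_var"].copy()
                i += 1


class Adam:
    """Adam optimizer over the parameters of a network."""

    def __init__(self, network, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for layer, name in self.network.parameters():
            key = (id(layer), name)
            g = layer.grads[name]
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
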