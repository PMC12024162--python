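"""Minimal convolutional network with explicit numpy forward/backward passes.

The localization method needs full access to every intermediate activation and
to the exact layer graph (for top-down importance propagation), so the network
is a plain list of small layer objects, each caching its forward input.  Only
the layer types the importance-propagation rules cover are provided: stride-1
2-D convolution, ReLU, non-overlapping max/average pooling, and the 1x1 score
projection.  All arrays are float64, batch-first: images are (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Scale",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "AvgPool2D",
    "ScoreProjection",
    "Network",
    "conv2d",
    "conv2d_input_grad",
]


def _pad(x: np.ndarray, pad: int, mode: str) -> np.ndarray:
    if not pad:
        return x
    spec = ((0, 0), (0, 0), (pad, pad), (pad, pad))
    if mode == "zeros":
        return np.pad(x, spec)
    if mode == "edge":
        return np.pad(x, spec, mode="edge")
    raise ValueError(f"unknown padding mode {mode!r}")


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None,
           pad: int = 0, pad_mode: str = "zeros") -> np.ndarray:
    """Stride-1 cross-correlation of (N,Cin,H,W) with (Cout,Cin,k,k)."""
    k = W.shape[-1]
    x = _pad(x, pad, pad_mode)
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,Cin,h,w,k,k
    n, _, h, w = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, -1)
    out = cols @ W.reshape(W.shape[0], -1).T
    if b is not None:
        out = out + b
    return out.transpose(0, 3, 1, 2)


def conv2d_input_grad(g: np.ndarray, W: np.ndarray, pad: int,
                      in_shape: tuple[int, ...],
                      pad_mode: str = "zeros") -> np.ndarray:
    """Gradient of ``conv2d`` w.r.t. its input (the transposed convolution).

    With edge (replicate) padding, gradient landing on padded cells is folded
    back onto the border pixels they replicate.
    """
    n, cout, h, w = g.shape
    _, cin, hin, win_ = in_shape
    k = W.shape[-1]
    gflat = g.transpose(0, 2, 3, 1)  # N,h,w,Cout
    dcols = gflat @ W.reshape(cout, -1)  # N,h,w,Cin*k*k
    dcols = dcols.reshape(n, h, w, cin, k, k)
    dxp = np.zeros((n, cin, hin + 2 * pad, win_ + 2 * pad))
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    if not pad:
        return dxp
    p = pad
    dx = dxp[:, :, p:-p, p:-p].copy()
    if pad_mode == "edge":
        dx[:, :, 0, :] += dxp[:, :, :p, p:-p].sum(axis=2)
        dx[:, :, -1, :] += dxp[:, :, -p:, p:-p].sum(axis=2)
        dx[:, :, :, 0] += dxp[:, :, p:-p, :p].sum(axis=3)
        dx[:, :, :, -1] += dxp[:, :, p:-p, -p:].sum(axis=3)
        dx[:, :, 0, 0] += dxp[:, :, :p, :p].sum(axis=(2, 3))
        dx[:, :, 0, -1] += dxp[:, :, :p, -p:].sum(axis=(2, 3))
        dx[:, :, -1, 0] += dxp[:, :, -p:, :p].sum(axis=(2, 3))
        dx[:, :, -1, -1] += dxp[:, :, -p:, -p:].sum(axis=(2, 3))
    return dx


class Layer:
    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; empty for parameter-free layers."""
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Scale(Layer):
    """Fixed positive rescaling of the input.

    Grayscale images in [0, 1] are dominated by a flat background, so their
    pixel standard deviation is far below one; rescaling by a positive
    constant brings activations (and hence gradients) of the convolution
    stack to unit order.  A positive one-to-one mapping is transparent to
    importance propagation: each unit has a single child with positive
    weight, so importance passes through unchanged.
    """

    def __init__(self, factor: float):
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        self.factor = float(factor)

    def forward(self, x):
        self.x = x
        return x * self.factor

    def backward(self, g):
        return g * self.factor


class Conv2D(Layer):
    """Stride-1 convolution with 'same' padding by default (pad = k // 2)."""

    #: treated as a weight for L2 regularisation purposes
    weight_names = ("W",)

    def __init__(self, c_in: int, c_out: int, ksize: int = 3,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 pad_mode: str = "edge"):
        self.k = ksize
        self.pad = ksize // 2 if pad is None else pad
        # replicate padding by default: a zero frame around bright images
        # creates strong spurious edge features in the score map
        self.pad_mode = pad_mode
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * ksize * ksize))  # He initialisation
        self.W = rng.normal(0.0, scale, (c_out, c_in, ksize, ksize))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.x: np.ndarray | None = None

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def forward(self, x):
        self.x = x
        return conv2d(x, self.W, self.b, self.pad, self.pad_mode)

    def backward(self, g):
        x, k, pad = self.x, self.k, self.pad
        n, cout, h, w = g.shape
        xp = _pad(x, pad, self.pad_mode)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, -1)
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.gW += (gflat.T @ cols.reshape(-1, cols.shape[-1])).reshape(self.W.shape)
        self.gb += g.sum(axis=(0, 2, 3))
        return conv2d_input_grad(g, self.W, pad, x.shape, self.pad_mode)


class ReLU(Layer):
    def forward(self, x):
        self.x = x
        return np.maximum(x, 0.0)

    def backward(self, g):
        return g * (self.x > 0)


class _Pool(Layer):
    def __init__(self, size: int = 2):
        self.size = size
        self.x: np.ndarray | None = None

    def _windows(self, x):
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"pooling size {s} does not divide spatial dims {h}x{w}")
        return x.reshape(n, c, h // s, s, w // s, s)


class MaxPool2D(_Pool):
    """Non-overlapping max pooling; gradient split equally among tied maxima."""

    def forward(self, x):
        self.x = x
        xr = self._windows(x)
        self.out = xr.max(axis=(3, 5))
        return self.out

    def backward(self, g):
        xr = self._windows(self.x)
        mask = xr == self.out[:, :, :, None, :, None]
        count = mask.sum(axis=(3, 5))
        share = (g / count)[:, :, :, None, :, None]
        dxr = mask * share
        n, c, h, w = self.x.shape
        return dxr.reshape(n, c, h, w)


class AvgPool2D(_Pool):
    def forward(self, x):
        self.x = x
        xr = self._windows(x)
        return xr.mean(axis=(3, 5))

    def backward(self, g):
        s = self.size
        n, c, h, w = self.x.shape
        g = g / (s * s)
        return np.broadcast_to(
            g[:, :, :, None, :, None], (n, c, h // s, s, w // s, s)
        ).reshape(n, c, h, w)


class ScoreProjection(Layer):
    """1x1 projection of the final feature map onto a single score channel.

    The binary head has exactly one output channel: S[i,j] = sum_c V[c] *
    M[c,i,j] + bias, with no activation applied.  The bias defaults to zero.
    """

    weight_names = ("V",)

    def __init__(self, c_in: int, rng: np.random.Generator | None = None,
                 bias: float = 0.0):
        rng = rng or np.random.default_rng(0)
        # Nonnegative (half-normal) init: the initial score map then reads as
        # activation energy, so salient regions start as positive local
        # maxima and the extremum head has a meaningful warm start instead of
        # a sign pattern inherited from initialisation noise.
        self.V = np.abs(rng.normal(0.0, np.sqrt(1.0 / c_in), c_in))
        self.b = np.array(float(bias))
        self.gV = np.zeros_like(self.V)
        self.gb = np.zeros_like(self.b)
        self.x: np.ndarray | None = None

    def params(self):
        return [("V", self.V, self.gV), ("b", self.b, self.gb)]

    def forward(self, M):  # (N,C,h,w) -> (N,h,w)
        self.x = M
        return np.tensordot(M, self.V, axes=([1], [0])) + self.b

    def backward(self, gS):  # (N,h,w) -> (N,C,h,w)
        self.gV += np.einsum("nhw,nchw->c", gS, self.x)
        self.gb += gS.sum()
        return gS[:, None, :, :] * self.V[None, :, None, None]


class Network:
    """Feature extractor (a list of layers) followed by the score projection."""

    def __init__(self, features: list[Layer], proj: ScoreProjection):
        self.features = features
        self.proj = proj

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (feature map M, score map S); activations stay cached."""
        for layer in self.features:
            x = layer.forward(x)
        return x, self.proj.forward(x)

    def backward_from_score(self, gS: np.ndarray) -> np.ndarray:
        g = self.proj.backward(gS)
        for layer in reversed(self.features):
            g = layer.backward(g)
        return g

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        return [*self.features, self.proj]

    def parameters(self):
        for li, layer in enumerate(self._layers()):
            for name, value, grad in layer.params():
                yield f"layer{li}.{name}", layer, name, value, grad

    def zero_grads(self):
        for layer in self._layers():
            for _, _, grad in layer.params():
                grad[...] = 0.0

    def weight_sq_norm(self) -> float:
        """Sum of squares over weight tensors (biases excluded)."""
        total = 0.0
        for layer in self._layers():
            wnames = getattr(layer, "weight_names", ())
            for name, value, _ in layer.params():
                if name in wnames:
                    total += float(np.sum(value * value))
        return total

    def add_weight_decay(self, lam: float):
        """Add lam * theta to the gradients of weight tensors."""
        if lam == 0.0:
            return
        for layer in self._layers():
            wnames = getattr(layer, "weight_names", ())
            for name, value, grad in layer.params():
                if name in wnames:
                    grad += lam * value

    def sgd_step(self, lr: float):
        for layer in self._layers():
            for _, value, grad in layer.params():
                value -= lr * grad

    def n_parameters(self) -> int:
        return sum(v.size for _, _, _, v, _ in self.parameters())

    # -- (de)serialisation --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: value.copy() for key, _, _, value, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for key, _, _, value, _ in self.parameters():
            value[...] = state[key]
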