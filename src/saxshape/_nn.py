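"""Minimal NumPy building blocks for the 3D convolutional auto-encoder.

Implements exactly the layers the coder needs — 3x3x3 same-padding
convolution (im2col + GEMM), 2x max pooling with ceil semantics, nearest
upsampling, dense layers, ReLU and a fused sigmoid/binary-cross-entropy
head — with explicit backpropagation and an Adam optimizer.  Everything is
float32 and deterministic given a seeded Generator in single-threaded mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, D, H, W) -> (B*D*H*W, C*27) patches with 1-voxel zero pad."""
    b, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
    # win: (B, C, D, H, W, 3, 3, 3) -> (B, D, H, W, C, 3, 3, 3)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    return np.ascontiguousarray(win).reshape(b * d * h * w, c * 27)


class Conv3D(Layer):
    """3^3 kernel, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = cin * 27
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3, 3)
        ).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self._cols = None
        self._shape = None

    @property
    def _few_channels(self) -> bool:
        # for few channel pairs the strided shift-accumulate beats
        # materializing the im2col workspace (27x the activation volume)
        return self.cin * self.cout <= 16

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        if self._few_channels:
            W = self.params["W"]
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
            y = np.empty((b, self.cout, d, h, w), dtype=x.dtype)
            y[:] = self.params["b"].reshape(1, -1, 1, 1, 1)
            for dx in range(3):
                for dy in range(3):
                    for dz in range(3):
                        src = xp[:, :, dx:dx + d, dy:dy + h, dz:dz + w]
                        for o in range(self.cout):
                            for ci in range(self.cin):
                                y[:, o] += W[o, ci, dx, dy, dz] * src[:, ci]
            if train:
                self._xp, self._shape = xp, x.shape
            return y
        cols = _im2col(x)
        Wm = self.params["W"].reshape(self.cout, -1)
        y = cols @ Wm.T + self.params["b"]
        if train:
            self._cols, self._shape = cols, x.shape
        return y.reshape(b, d, h, w, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, dy, need_dx=True):
        b, co, d, h, w = dy.shape
        if self._few_channels:
            dW = np.empty_like(self.params["W"])
            for dxo in range(3):
                for dyo in range(3):
                    for dzo in range(3):
                        src = self._xp[:, :, dxo:dxo + d, dyo:dyo + h,
                                       dzo:dzo + w]
                        for o in range(self.cout):
                            for ci in range(self.cin):
                                dW[o, ci, dxo, dyo, dzo] = np.einsum(
                                    "bdhw,bdhw->", src[:, ci], dy[:, o])
            self.grads["W"] = dW
            self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
            self._xp = None
        else:
            dyf = dy.transpose(0, 2, 3, 4, 1).reshape(-1, co)
            self.grads["W"] = (dyf.T @ self._cols).reshape(
                self.params["W"].shape)
            self.grads["b"] = dyf.sum(axis=0)
            self._cols = None
        if not need_dx:
            return None
        # input gradient = convolution of dy with the flipped kernel,
        # channels swapped — same im2col machinery applies
        Wflip = self.params["W"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols_dy = _im2col(dy)
        dx = cols_dy @ Wflip.reshape(self.cin, -1).T
        return dx.reshape(b, d, h, w, self.cin).transpose(0, 4, 1, 2, 3)


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2, ceil mode (odd dims padded with -inf)."""

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        pd, ph, pw = d % 2, h % 2, w % 2
        if pd or ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        b, c, d2, h2, w2 = x.shape
        blocks = x.reshape(b, c, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d2 // 2, h2 // 2, w2 // 2, 8)
        if train:
            self._arg = blocks.argmax(axis=-1)
            self._inshape = (d, h, w) if not (pd or ph or pw) else (
                d2 - pd, h2 - ph, w2 - pw)
            self._padded = (d2, h2, w2)
        return blocks.max(axis=-1)

    def backward(self, dy):
        b, c, d, h, w = dy.shape
        d2, h2, w2 = self._padded
        out = np.zeros((b, c, d, h, w, 8), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(b, c, d, h, w, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d2, h2, w2)
        di, hi, wi = self._inshape
        return out[:, :, :di, :hi, :wi]


class Upsample3D(Layer):
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        b, c, d, h, w = dy.shape
        return dy.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(
            axis=(3, 5, 7))


class Crop3D(Layer):
    """Crop trailing voxels (e.g. 32^3 -> 31^3 after the last upsample)."""

    def __init__(self, target: int) -> None:
        super().__init__()
        self.target = target

    def forward(self, x, train=False):
        self._inshape = x.shape
        t = self.target
        return x[:, :, :t, :t, :t]

    def backward(self, dy):
        out = np.zeros(self._inshape, dtype=dy.dtype)
        t = self.target
        out[:, :, :t, :t, :t] = dy
        return out


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(np.float32)
        self.params["b"] = np.zeros(nout, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss_and_grad(logits: np.ndarray,
                      targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-voxel binary cross-entropy and its gradient w.r.t. logits."""
    p = sigmoid(logits)
    eps = 1e-7
    loss = -(targets * np.log(p + eps)
             + (1 - targets) * np.log(1 - p + eps)).mean()
    grad = (p - targets) / targets.size
    return float(loss), grad.astype(np.float32)


def run_forward(layers: list[Layer], x: np.ndarray,
                train: bool = False) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def run_backward(layers: list[Layer], dy: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
    for i, layer in enumerate(reversed(layers)):
        last = i == len(layers) - 1
        if isinstance(layer, Conv3D):
            dy = layer.backward(dy, need_dx=need_input_grad or not last)
        else:
            dy = layer.backward(dy)
    return dy


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def parameter_count(layers: list[Layer]) -> int:
    return sum(p.size for ly in layers for p in ly.params.values())


def get_state(layers: list[Layer]) -> list[dict]:
    return [{k: v.copy() for k, v in ly.params.items()} for ly in layers]


def set_state(layers: list[Layer], state: list[dict]) -> None:
    for ly, st in zip(layers, state):
        for k in ly.params:
            ly.params[k] = st[k].copy()
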