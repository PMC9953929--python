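"""Minimal numpy execution backend for the 3D CNN architecture specs.

Implements exactly the layer set the architecture module declares —
same-padded stride-1 3D convolution (im2col), max-pooling with kernel ==
stride and ceil rounding (padding with -inf), flatten, dense, inverted
dropout — together with softmax cross-entropy with per-class weights, L2
weight decay, and Adam. Forward and backward passes are vectorized numpy;
weights are float32, He-initialized.

The built network's introspected trainable-parameter count equals the
closed-form count of its spec by construction, and traced layer output
shapes equal the spec's shape propagation; both equivalences are enforced
by tests.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .architecture import ArchitectureSpec, forward_shapes

__all__ = ["Network", "build_model", "AdamOptimizer", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Param:
    """A trainable array with its gradient and weight-decay flag."""

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool):
        self.name = name
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay


class _Layer:
    params: list[Param] = []

    def forward(self, x, train: bool, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(_Layer):
    """Same-padded stride-1 3D convolution with optional ReLU, via im2col."""

    def __init__(self, name, c_in, c_out, kernel, relu, l2, rng):
        self.name = name
        self.kernel = tuple(kernel)
        self.relu = relu
        k = math.prod(self.kernel)
        fan_in = c_in * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in) + self.kernel)
        self.W = Param(f"{name}.W", w, decay=l2)
        self.b = Param(f"{name}.b", np.zeros(c_out), decay=False)
        self.params = [self.W, self.b]

    def _im2col(self, x):
        # x: (N, C, D, H, W) zero-padded; windows -> (N, D, H, W, C*k^3)
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        # win: (N, C, D, H, W, kd, kh, kw) -> (N, D, H, W, C, kd, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        n, d, h, w = cols.shape[:4]
        return cols.reshape(n, d, h, w, -1)

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        cols = self._im2col(x)
        self.cols = cols if train else None
        c_out = self.W.value.shape[0]
        wmat = self.W.value.reshape(c_out, -1)
        z = cols @ wmat.T + self.b.value
        z = z.transpose(0, 4, 1, 2, 3)
        if self.relu:
            self.mask = z > 0 if train else None
            z = np.maximum(z, 0.0)
        return z

    def backward(self, dout):
        if self.relu:
            dout = dout * self.mask
        n, c_out, d, h, w = dout.shape
        dy = dout.transpose(0, 2, 3, 4, 1).reshape(-1, c_out)  # (NDHW, C_out)
        cols2 = self.cols.reshape(-1, self.cols.shape[-1])
        self.W.grad[...] = (dy.T @ cols2).reshape(self.W.value.shape)
        self.b.grad[...] = dy.sum(axis=0)
        wmat = self.W.value.reshape(c_out, -1)
        dcols = (dy @ wmat).reshape(n, d, h, w, -1)
        # scatter-add back to the padded input (col2im)
        _, c_in, dd, hh, ww = self.x_shape
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        dcols = dcols.reshape(n, d, h, w, c_in, kd, kh, kw)
        dxp = np.zeros((n, c_in, dd + 2 * pd, hh + 2 * ph, ww + 2 * pw), dtype=np.float32)
        for i in range(kd):
            for j in range(kh):
                for l in range(kw):
                    dxp[:, :, i : i + d, j : j + h, l : l + w] += dcols[
                        :, :, :, :, :, i, j, l
                    ].transpose(0, 4, 1, 2, 3)
        self.cols = None
        return dxp[:, :, pd : pd + dd, ph : ph + hh, pw : pw + ww]


class MaxPool3D(_Layer):
    """Max pooling with kernel == stride; ceil rounding via -inf padding."""

    def __init__(self, name, stride, rounding="ceil"):
        self.name = name
        self.stride = tuple(stride)
        self.rounding = rounding
        self.params = []

    def forward(self, x, train, rng):
        n, c, d, h, w = x.shape
        sd, sh, sw = self.stride
        if self.rounding == "ceil":
            od, oh, ow = math.ceil(d / sd), math.ceil(h / sh), math.ceil(w / sw)
        else:
            od, oh, ow = d // sd, h // sh, w // sw
        pad = (od * sd - d, oh * sh - h, ow * sw - w)
        self.in_shape, self.pad = x.shape, pad
        if self.rounding == "floor" and any(p < 0 for p in pad):  # truncate tail
            x = x[:, :, : od * sd, : oh * sh, : ow * sw]
            pad = (0, 0, 0)
            self.pad = pad
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (0, pad[0]), (0, pad[1]), (0, pad[2])),
            constant_values=-np.inf,
        )
        blocks = (
            xp.reshape(n, c, od, sd, oh, sh, ow, sw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, od, oh, ow, sd * sh * sw)
        )
        self.argmax = blocks.argmax(axis=-1) if train else None
        out = blocks.max(axis=-1)
        self.out_shape = out.shape
        return out

    def backward(self, dout):
        n, c, od, oh, ow = self.out_shape
        sd, sh, sw = self.stride
        dblocks = np.zeros((n, c, od, oh, ow, sd * sh * sw), dtype=np.float32)
        np.put_along_axis(dblocks, self.argmax[..., None], dout[..., None], axis=-1)
        dxp = (
            dblocks.reshape(n, c, od, oh, ow, sd, sh, sw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, od * sd, oh * sh, ow * sw)
        )
        _, _, d, h, w = self.in_shape
        self.argmax = None
        return dxp[:, :, :d, :h, :w]


class Flatten(_Layer):
    def __init__(self, name):
        self.name = name
        self.params = []

    def forward(self, x, train, rng):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.in_shape)


class Dense(_Layer):
    """Fully connected layer; ReLU applied here, softmax deferred to the loss."""

    def __init__(self, name, fan_in, units, activation, l2, rng):
        self.name = name
        self.activation = activation
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(units, fan_in))
        self.W = Param(f"{name}.W", w, decay=l2)
        self.b = Param(f"{name}.b", np.zeros(units), decay=False)
        self.params = [self.W, self.b]

    def forward(self, x, train, rng):
        self.x = x if train else None
        z = x @ self.W.value.T + self.b.value
        if self.activation == "relu":
            self.mask = z > 0 if train else None
            z = np.maximum(z, 0.0)
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self.mask
        self.W.grad[...] = dout.T @ self.x
        self.b.grad[...] = dout.sum(axis=0)
        dx = dout @ self.W.value
        self.x = None
        return dx


class Dropout(_Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, name, rate):
        self.name = name
        self.rate = rate
        self.params = []
        self.mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self.mask

    def backward(self, dout):
        if self.mask is None:
            return dout
        return dout * self.mask


class Network:
    """A runnable model built from an :class:`ArchitectureSpec`.

    ``forward`` maps a batch to logits; :meth:`predict_proba` applies the
    softmax so per-class probabilities sum to one per sample. The loss is
    softmax cross-entropy with optional per-sample weights plus L2 decay on
    flagged kernels.
    """

    def __init__(self, spec: ArchitectureSpec, layers: list[_Layer], l2: float):
        self.spec = spec
        self.layers = layers
        self.l2 = l2

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def trace_shapes(self, x: np.ndarray) -> list[tuple]:
        """Per-layer output shapes (without the batch axis) of an actual pass."""
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, train=False, rng=None)
            shapes.append(tuple(x.shape[1:]))
        return shapes

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def loss_and_grad(
        self, x: np.ndarray, y: np.ndarray, sample_weight: np.ndarray, rng
    ) -> float:
        """Weighted cross-entropy + L2; populates parameter gradients."""
        n = x.shape[0]
        logits = self.forward(x, train=True, rng=rng)
        p = softmax(logits)
        eps = 1e-12
        data_loss = float(
            -(sample_weight * np.log(p[np.arange(n), y] + eps)).sum() / n
        )
        reg = self.l2 * sum(float(np.square(p_.value).sum()) for p_ in self.params if p_.decay)
        dlogits = p
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (sample_weight / n)[:, None]
        dout = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        if self.l2:
            for p_ in self.params:
                if p_.decay:
                    p_.grad += 2.0 * self.l2 * p_.value
        return data_loss + reg

    def eval_loss(self, x: np.ndarray, y: np.ndarray, sample_weight: np.ndarray) -> float:
        logits = self.forward(x, train=False)
        p = softmax(logits)
        n = x.shape[0]
        data_loss = float(-(sample_weight * np.log(p[np.arange(n), y] + 1e-12)).sum() / n)
        reg = self.l2 * sum(float(np.square(p_.value).sum()) for p_ in self.params if p_.decay)
        return data_loss + reg

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.value[...] = w

    def weight_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.params:
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


class AdamOptimizer:
    """Adam with the conventional defaults (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


def build_model(
    spec: ArchitectureSpec, l2: float = 1e-4, seed: int | None = None,
    dropout_override: float | None = None,
) -> Network:
    """Instantiate a runnable :class:`Network` from an architecture spec.

    The trainable-parameter count of the result equals the spec's
    closed-form count exactly. ``dropout_override`` replaces the rate of
    every dropout layer (a training hyperparameter in the grid search).
    """
    rng = np.random.default_rng(seed)
    shapes = forward_shapes(spec)
    layers: list[_Layer] = []
    channels = spec.input_channels
    units: int | None = None
    try:
        for layer, shape in zip(spec.layers, shapes):
            if layer.kind == "conv3d":
                layers.append(
                    Conv3D(
                        layer.name, channels, layer.channels_out, layer.kernel,
                        relu=layer.activation == "relu",
                        l2=layer.regularization == "l2", rng=rng,
                    )
                )
                channels = layer.channels_out
            elif layer.kind == "maxpool3d":
                layers.append(MaxPool3D(layer.name, layer.stride, layer.pool_rounding))
            elif layer.kind == "flatten":
                layers.append(Flatten(layer.name))
            elif layer.kind == "dense":
                layers.append(
                    Dense(
                        layer.name, units, layer.units,
                        activation=layer.activation,
                        l2=layer.regularization == "l2", rng=rng,
                    )
                )
            elif layer.kind == "dropout":
                rate = layer.rate if dropout_override is None else dropout_override
                layers.append(Dropout(layer.name, rate))
            elif layer.kind == "concat_inputs":
                pass  # pure bookkeeping: input arrives pre-concatenated
            if shape.units is not None:
                units = shape.units
    except Exception as exc:
        raise RuntimeError(f"building model for spec '{spec.name}' failed: {exc}") from exc
    return Network(spec, layers, l2=l2)
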