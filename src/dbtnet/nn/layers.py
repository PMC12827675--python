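"""Minimal feed-forward neural-network layers on numpy with hand-derived backprop.

Every layer is a :class:`Module` exposing ``forward(x)`` and ``backward(grad_y)``;
``backward`` returns the gradient with respect to the layer input and accumulates
parameter gradients in-place.  Layers cache whatever the backward pass needs during
``forward``, so a backward call must follow the forward call it refers to.

Shapes follow the NCHW convention: ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: parameter discovery, train/eval mode, optional activation taps.

    When ``retain`` is set (used by Grad-CAM), :class:`Sequential` stores the
    module's output in ``last_output`` and the upstream gradient of that output in
    ``last_grad`` during the backward pass.
    """

    training: bool = False
    retain: bool = False
    last_output: np.ndarray | None = None
    last_grad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- recursive traversal -------------------------------------------------
    def children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self) -> list[Param]:
        seen: list[Param] = []
        for mod in self.modules():
            for value in vars(mod).values():
                if isinstance(value, Param):
                    seen.append(value)
        return seen

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, flag: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters + buffers) in traversal order."""
        arrays: list[np.ndarray] = []
        for mod in self.modules():
            for name, value in sorted(vars(mod).items()):
                if isinstance(value, Param):
                    arrays.append(value.data)
                elif isinstance(value, np.ndarray) and name.startswith("running_"):
                    arrays.append(value)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model expects {len(targets)}"
            )
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    """2-D cross-correlation with stride, symmetric zero padding and groups.

    ``groups == in_channels`` gives a depthwise convolution.  The im2col view is
    taken with :func:`sliding_window_view`, so the forward pass is a single einsum.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 pad: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        if in_ch % groups or out_ch % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.pad, self.groups = stride, pad, groups
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Param(_fan_in_uniform(rng, (groups, out_ch // groups,
                                                  in_ch // groups, kernel, kernel),
                                            fan_in))
        self.bias = Param(_fan_in_uniform(rng, (out_ch,), fan_in)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p, g = self.kernel, self.stride, self.pad, self.groups
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        wing = win.reshape(n, g, c // g, ho, wo, k, k)
        y = np.einsum("ngchwij,gocij->ngohw", wing, self.weight.data, optimize=True)
        y = y.reshape(n, self.out_ch, ho, wo)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (wing, xp.shape, ho, wo)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        wing, xp_shape, ho, wo = self._cache
        n = gy.shape[0]
        k, s, p, g = self.kernel, self.stride, self.pad, self.groups
        gyg = gy.reshape(n, g, self.out_ch // g, ho, wo)
        self.weight.grad += np.einsum("ngohw,ngchwij->gocij", gyg, wing,
                                      optimize=True)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        gwin = np.einsum("ngohw,gocij->ngchwij", gyg, self.weight.data,
                         optimize=True).reshape(n, self.in_ch, ho, wo, k, k)
        gxp = np.zeros((n, self.in_ch) + xp_shape[2:])
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gwin[:, :, :, :, i, j]
        return gxp[:, :, p:gxp.shape[2] - p, p:gxp.shape[3] - p] if p else gxp


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Param(_fan_in_uniform(rng, (out_features, in_features),
                                            in_features))
        self.bias = Param(_fan_in_uniform(rng, (out_features,), in_features))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got {x.shape[-1]}")
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.data


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return gy * self._mask


class ReLU6(Module):
    """Clipped rectifier used by the MobileNetV2 blocks."""

    def forward(self, x):
        self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, gy):
        return gy * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        orig_shape = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = win.max(axis=(4, 5))
        # tie-splitting mask keeps the gradient well-defined on plateaus
        mask = (win == y[..., None, None]).astype(np.float64)
        mask /= mask.sum(axis=(4, 5), keepdims=True)
        self._cache = (mask, orig_shape)
        return y

    def backward(self, gy):
        mask, x_shape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = gy.shape[2], gy.shape[3]
        padded_shape = (x_shape[0], x_shape[1], x_shape[2] + 2 * p,
                        x_shape[3] + 2 * p)
        gx = np.zeros(padded_shape)
        weighted = mask * gy[..., None, None]
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += weighted[:, :, :, :, i, j]
        return gx[:, :, p:padded_shape[2] - p, p:padded_shape[3] - p] if p else gx


class AvgPool2d(Module):
    """Non-overlapping average pooling (kernel == stride)."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x):
        k = self.kernel
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, gy):
        k = self.kernel
        gx = np.repeat(np.repeat(gy, k, axis=2), k, axis=3) / (k * k)
        return gx


class AdaptiveAvgPool2d(Module):
    """Average pooling to a fixed output grid, with torch-style bin edges."""

    def __init__(self, out_size: int = 1):
        self.out_size = out_size

    @staticmethod
    def _edges(n: int, out: int):
        starts = (np.arange(out) * n) // out
        ends = -(-(np.arange(1, out + 1) * n) // out)  # ceil division
        return starts, ends

    def forward(self, x):
        n, c, h, w = x.shape
        o = self.out_size
        if o == 1:
            self._cache = (x.shape, None)
            return x.mean(axis=(2, 3), keepdims=True)
        hs, he = self._edges(h, o)
        ws, we = self._edges(w, o)
        y = np.empty((n, c, o, o))
        for i in range(o):
            for j in range(o):
                y[:, :, i, j] = x[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))
        self._cache = (x.shape, (hs, he, ws, we))
        return y

    def backward(self, gy):
        x_shape, bins = self._cache
        gx = np.zeros(x_shape)
        if bins is None:
            gx += gy / (x_shape[2] * x_shape[3])
            return gx
        hs, he, ws, we = bins
        for i in range(self.out_size):
            for j in range(self.out_size):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                gx[:, :, hs[i]:he[i], ws[j]:we[j]] += \
                    gy[:, :, i:i + 1, j:j + 1] / area
        return gx


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1):
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        self._cache = (xhat, ivstd, x.shape)
        return xhat * self.gamma.data[None, :, None, None] + \
            self.beta.data[None, :, None, None]

    def backward(self, gy):
        xhat, ivstd, x_shape = self._cache
        m = x_shape[0] * x_shape[2] * x_shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.data[None, :, None, None]
        if not self.training:
            return gxhat * ivstd[None, :, None, None]
        sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (gxhat - sum_g / m - xhat * sum_gx / m) * ivstd[None, :, None, None]


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x):
        for mod in self.layers:
            x = mod(x)
            if mod.retain:
                mod.last_output = x
        return x

    def backward(self, gy):
        for mod in reversed(self.layers):
            if mod.retain:
                mod.last_grad = gy
            gy = mod.backward(gy)
        return gy


class Residual(Module):
    """``act(body(x) + shortcut(x))``; identity shortcut when none is given."""

    def __init__(self, body: Module, shortcut: Module | None = None,
                 activation: str = "relu"):
        self.body = body
        self.shortcut = shortcut
        if activation not in ("relu", "none"):
            raise ValueError("activation must be 'relu' or 'none'")
        self.activation = activation

    def forward(self, x):
        y = self.body(x) + (self.shortcut(x) if self.shortcut is not None else x)
        if self.activation == "relu":
            self._mask = y > 0
            return np.where(self._mask, y, 0.0)
        return y

    def backward(self, gy):
        if self.activation == "relu":
            gy = gy * self._mask
        gx = self.body.backward(gy)
        gx = gx + (self.shortcut.backward(gy) if self.shortcut is not None else gy)
        return gx


class DenseBlock(Module):
    """Densely connected block: each layer sees the concat of all earlier outputs."""

    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def forward(self, x):
        feats = [x]
        widths = [x.shape[1]]
        for layer in self.layers:
            out = layer(np.concatenate(feats, axis=1))
            feats.append(out)
            widths.append(out.shape[1])
        self._widths = widths
        return np.concatenate(feats, axis=1)

    def backward(self, gy):
        splits = np.cumsum(self._widths)[:-1]
        gfeats = list(np.split(gy, splits, axis=1))
        for idx in range(len(self.layers) - 1, -1, -1):
            gin = self.layers[idx].backward(gfeats[idx + 1])
            gparts = np.split(gin, np.cumsum(self._widths[:idx + 1])[:-1], axis=1)
            for k, part in enumerate(gparts):
                gfeats[k] = gfeats[k] + part
        return gfeats[0]
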