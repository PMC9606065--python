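"""Minimal CPU conv-net layers with explicit backpropagation.

Implements exactly the operations the image-translation networks need:
2D convolution (strided, grouped) via im2col, average pooling, nearest
upsampling, instance normalization, ReLU/LeakyReLU/Tanh, residual blocks,
and an Adam optimizer. Data layout is (N, C, H, W), float32 by default.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``grads`` (call ``zero_grad`` before
each optimization step). Gradients are validated against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "AvgPool2d",
    "UpsampleNearest2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "ResBlock",
    "Adam",
]


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def layers(self):
        """All parameterized leaf layers under this one (including self)."""
        yield self

    def zero_grad(self) -> None:
        for lyr in self.layers():
            for k, p in lyr.params.items():
                lyr.grads[k] = np.zeros_like(p)

    def n_parameters(self) -> int:
        return sum(p.size for lyr in self.layers() for p in lyr.params.values())

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _accum(grads: dict, key: str, value: np.ndarray) -> None:
    if key in grads:
        grads[key] += value
    else:
        grads[key] = value


class Conv2d(Layer):
    """2D convolution (cross-correlation) with stride, zero padding, groups.

    With ``groups=g`` the input and output channels are split into ``g``
    disjoint groups with no cross-group connections — the first-layer
    modality separation used by the PET/CT group-convolution variant.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}"
            )
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride = stride
        self.padding = (kernel_size - 1) // 2 if padding is None else padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((out_channels, in_channels // groups, kernel_size, kernel_size))
        else:
            w = rng.normal(0.0, 0.02, (out_channels, in_channels // groups, kernel_size, kernel_size))
        self.params["w"] = w.astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p, g = self.k, self.stride, self.padding, self.groups
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cg, og = self.cin // g, self.cout // g
        wk = self.params["w"]  # (cout, cg, k, k)
        # accumulate one small matmul per kernel offset: channels-last layout
        # keeps every slice copy contiguous and cheap
        out = np.zeros((g, n, ho, wo, og), dtype=x.dtype)
        for gi in range(g):
            csl = slice(gi * cg, (gi + 1) * cg)
            osl = slice(gi * og, (gi + 1) * og)
            for i in range(k):
                for j in range(k):
                    xs = xp[:, csl, i : i + s * ho : s, j : j + s * wo : s]
                    out[gi] += np.ascontiguousarray(xs.transpose(0, 2, 3, 1)) @ wk[osl, :, i, j].T
            out[gi] += self.params["b"][osl]
        self._cache = (xp, ho, wo)
        merged = np.concatenate([out[gi].transpose(0, 3, 1, 2) for gi in range(g)], axis=1)
        return np.ascontiguousarray(merged)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, ho, wo = self._cache
        k, s, p, g = self.k, self.stride, self.padding, self.groups
        cg, og = self.cin // g, self.cout // g
        wk = self.params["w"]
        dw = np.zeros(wk.shape, dtype=np.float64)
        db = np.zeros(self.cout, dtype=np.float64)
        dxp = np.zeros(xp.shape, dtype=dout.dtype)
        for gi in range(g):
            csl = slice(gi * cg, (gi + 1) * cg)
            osl = slice(gi * og, (gi + 1) * og)
            dg = np.ascontiguousarray(dout[:, osl].transpose(0, 2, 3, 1))  # (n, ho, wo, og)
            db[osl] = dg.sum(axis=(0, 1, 2))
            for i in range(k):
                for j in range(k):
                    xs = xp[:, csl, i : i + s * ho : s, j : j + s * wo : s]
                    xs_cl = np.ascontiguousarray(xs.transpose(0, 2, 3, 1))  # (n, ho, wo, cg)
                    dw[osl, :, i, j] = np.tensordot(dg, xs_cl, axes=([0, 1, 2], [0, 1, 2]))
                    dxs = dg @ wk[osl, :, i, j]  # (n, ho, wo, cg)
                    dxp[:, csl, i : i + s * ho : s, j : j + s * wo : s] += dxs.transpose(
                        0, 3, 1, 2
                    )
        _accum(self.grads, "w", dw.astype(self.params["w"].dtype))
        _accum(self.grads, "b", db.astype(self.params["b"].dtype))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class AvgPool2d(Layer):
    """2x2 average pooling (spatial dims must be even)."""

    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size must be even for 2x2 pooling, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3)
        return up / 4.0


class UpsampleNearest2d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class InstanceNorm2d(Layer):
    """Per-sample per-channel normalization over the spatial dims, affine."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["gamma"][None, :, None, None]
        _accum(self.grads, "gamma", (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32))
        _accum(self.grads, "beta", dout.sum(axis=(0, 2, 3)).astype(np.float32))
        dxhat = dout * g
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._out**2)


class Sequential(Layer):
    def __init__(self, children: list[Layer]) -> None:
        super().__init__()
        self.children = list(children)

    def layers(self):
        for child in self.children:
            yield from child.layers()

    def forward(self, x: np.ndarray) -> np.ndarray:
        for child in self.children:
            x = child.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for child in reversed(self.children):
            dout = child.backward(dout)
        return dout


class ResBlock(Layer):
    """conv3x3 - IN - ReLU - conv3x3 - IN with identity skip."""

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.body = Sequential(
            [
                Conv2d(channels, channels, 3, rng=rng),
                InstanceNorm2d(channels),
                ReLU(),
                Conv2d(channels, channels, 3, rng=rng),
                InstanceNorm2d(channels),
            ]
        )

    def layers(self):
        yield from self.body.layers()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.body.backward(dout)


class Adam:
    """Adam over all parameters of one or more networks.

    Defaults follow the GAN-training convention beta1=0.5, beta2=0.999.
    """

    def __init__(self, nets, lr: float, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        if not isinstance(nets, (list, tuple)):
            nets = [nets]
        self.slots = [(lyr, key) for net in nets for lyr in net.layers() for key in lyr.params]
        self.m = [np.zeros_like(lyr.params[k]) for lyr, k in self.slots]
        self.v = [np.zeros_like(lyr.params[k]) for lyr, k in self.slots]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (lyr, key) in enumerate(self.slots):
            g = lyr.grads.get(key)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            lyr.params[key] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                lyr.params[key].dtype
            )
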