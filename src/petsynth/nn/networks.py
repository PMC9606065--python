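"""Coarse-to-fine generator and multi-scale patch discriminator.

The generator pairs a *global* network, operating on a 2x-downsampled copy
of the input, with a *local enhancer* operating at full resolution; the
global network's final feature map is added to the enhancer's encoded
features before the enhancer's residual blocks, so local detail is
synthesized on top of globally consistent structure.

Both encoders open with a 7x7 convolution (optionally a 2-group convolution
that processes the PET channels 0-2 and CT channels 3-5 with disjoint filter
groups) and downsample with stride-1 convolutions followed by 2x2 average
pooling. The output head is a 7x7 convolution with tanh, so outputs live in
(-1, 1) at the input resolution.

The discriminator is a patch classifier applied at three image scales
(full, 1/2, 1/4 average-pooled); each scale exposes its intermediate
activations for the feature-matching loss.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AvgPool2d,
    Conv2d,
    InstanceNorm2d,
    Layer,
    LeakyReLU,
    ReLU,
    ResBlock,
    Sequential,
    Tanh,
    UpsampleNearest2d,
)

__all__ = ["Generator", "PatchDiscriminator"]


def _encoder_front(cin: int, width: int, ksize: int, groups: int, rng) -> list[Layer]:
    return [
        Conv2d(cin, width, ksize, groups=groups, rng=rng),
        InstanceNorm2d(width),
        ReLU(),
    ]


def _down_stage(cin: int, cout: int, rng) -> list[Layer]:
    # stride-1 convolution followed by average pooling (the "average pooling
    # in the encoders" downsampling variant)
    return [Conv2d(cin, cout, 3, rng=rng), InstanceNorm2d(cout), ReLU(), AvgPool2d()]


def _up_stage(cin: int, cout: int, rng) -> list[Layer]:
    return [UpsampleNearest2d(), Conv2d(cin, cout, 3, rng=rng), InstanceNorm2d(cout), ReLU()]


class Generator(Layer):
    """Coarse-to-fine image-translation generator.

    Parameters mirror the network config: ``base_width`` is the channel
    width at full resolution inside the global network (the enhancer runs at
    half that width), ``n_downsamples``/``n_resblocks`` size the global
    network, ``groups=2`` enables the PET/CT group convolution in both
    encoder fronts. ``zero_init_final`` zero-initializes the output head
    (test hook: makes an untrained generator output exactly tanh(0)=0).
    """

    def __init__(
        self,
        in_channels: int,
        base_width: int = 16,
        n_downsamples: int = 2,
        n_resblocks: int = 2,
        n_local_resblocks: int = 1,
        initial_filter_size: int = 7,
        out_channels: int = 1,
        groups: int = 1,
        seed: int = 0,
        zero_init_final: bool = False,
    ) -> None:
        super().__init__()
        if groups > 1 and in_channels % groups:
            raise ValueError(
                f"group convolution needs input channels divisible by {groups}, got {in_channels}"
            )
        if base_width % max(groups, 1):
            raise ValueError("base_width must be divisible by the group count")
        rng = np.random.default_rng(seed)
        w = base_width
        self.in_channels = in_channels
        self.pool = AvgPool2d()

        # global network: runs on the 2x-downsampled input, returns features
        # of width w at half the full resolution
        glob: list[Layer] = _encoder_front(in_channels, w, initial_filter_size, groups, rng)
        widths = [w]
        for _ in range(n_downsamples):
            widths.append(min(widths[-1] * 2, 4 * w))
            glob += _down_stage(widths[-2], widths[-1], rng)
        glob += [ResBlock(widths[-1], rng) for _ in range(n_resblocks)]
        for i in range(n_downsamples, 0, -1):
            glob += _up_stage(widths[i], widths[i - 1], rng)
        self.global_net = Sequential(glob)

        # local enhancer: full-resolution encoder down to half resolution,
        # where the global features are added
        we = max(w // 2, max(groups, 1))
        if we % max(groups, 1):
            we += 1
        self.enh_front = Sequential(
            _encoder_front(in_channels, we, initial_filter_size, groups, rng)
            + _down_stage(we, w, rng)
        )
        self.enh_back = Sequential(
            [ResBlock(w, rng) for _ in range(n_local_resblocks)]
            + _up_stage(w, we, rng)
            + [
                Conv2d(we, out_channels, initial_filter_size, rng=rng, zero_init=zero_init_final),
                Tanh(),
            ]
        )

    def layers(self):
        yield from self.global_net.layers()
        yield from self.enh_front.layers()
        yield from self.enh_back.layers()

    def forward(self, x: np.ndarray) -> np.ndarray:
        f_global = self.global_net.forward(self.pool.forward(x))
        f_local = self.enh_front.forward(x)
        return self.enh_back.forward(f_global + f_local)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        df = self.enh_back.backward(dout)
        dx = self.enh_front.backward(df)
        dx_global = self.pool.backward(self.global_net.backward(df))
        return dx + dx_global

    def first_conv(self) -> Conv2d:
        """The global encoder's opening convolution (group-conv inspection)."""
        return self.global_net.children[0]  # type: ignore[return-value]


class PatchDiscriminator(Layer):
    """PatchGAN classifier returning per-patch scores and layer features.

    ``forward`` returns ``(score, feats)`` where ``feats`` are the
    activations after each block — the inputs to the feature-matching loss.
    ``backward`` accepts a gradient for the score and one per feature map,
    and returns the gradient with respect to the (condition, image) input.
    """

    def __init__(self, in_channels: int, ndf: int = 16, n_layers: int = 2, seed: int = 0) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        blocks: list[Sequential] = [
            Sequential([Conv2d(in_channels, ndf, 4, stride=2, padding=1, rng=rng), LeakyReLU(0.2)])
        ]
        width = ndf
        for _ in range(1, n_layers):
            nxt = min(width * 2, 8 * ndf)
            blocks.append(
                Sequential(
                    [
                        Conv2d(width, nxt, 4, stride=2, padding=1, rng=rng),
                        InstanceNorm2d(nxt),
                        LeakyReLU(0.2),
                    ]
                )
            )
            width = nxt
        blocks.append(Sequential([Conv2d(width, 1, 4, stride=1, padding=1, rng=rng)]))
        self.blocks = blocks

    @property
    def n_feature_layers(self) -> int:
        return len(self.blocks)

    def layers(self):
        for b in self.blocks:
            yield from b.layers()

    def forward(self, x: np.ndarray):
        feats = []
        for b in self.blocks:
            x = b.forward(x)
            feats.append(x)
        return x, feats

    def backward(self, dscore: np.ndarray, dfeats: list[np.ndarray] | None = None) -> np.ndarray:
        grad = dscore
        for i in reversed(range(len(self.blocks))):
            if dfeats is not None and dfeats[i] is not None:
                grad = grad + dfeats[i]
            grad = self.blocks[i].backward(grad)
        return grad
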