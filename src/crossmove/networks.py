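"""1D generator and patch-discriminator architectures.

The generator is the ResNet encoder/transformer/decoder of the
image-translation literature, flattened to one dimension: a wide-kernel
input convolution, two stride-2 downsampling convolutions, nine residual
blocks, two upsampling stages and a wide-kernel output convolution with
a sigmoid (signals live in [0, 1]).  Instance normalization (affine-free)
follows every convolution except the output.

The discriminator is a 70x1 PatchGAN: stacked kernel-4 convolutions
(stride 2, 2, 2, 1, 1) with leaky-ReLU slope 0.2, emitting one real/fake
score per 70-sample receptive field.  No normalization layers, so the
receptive field of each patch score is exactly the convolutional one.

Subject conditioning: the one-hot class vector is tiled along the time
axis and concatenated to the signal as extra input channels, for both
generators and discriminators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture hyperparameters of the translation generator."""

    input_length: int = 256
    base_filters: int = 64
    edge_kernel: int = 7          # first and last convolution
    inner_kernel: int = 3         # downsampling/upsampling/residual convs
    n_resnet_blocks: int = 9
    n_downsample: int = 2         # stride-2 stages (mirrored on the way up)
    output_channels: int = 1
    init_mean: float = 0.0
    init_sd: float = 0.02
    output_activation: str = "sigmoid"
    #: "instance" (per-channel, across time, affine-free) follows the
    #: reference encoder/decoder generator; "channel" (per-time-step,
    #: across channels) is available as an alternative that preserves
    #: constant-in-time information such as the tiled class condition.
    norm: str = "instance"
    #: normalize the first encoder convolution's output.  When False the
    #: tiled class condition passes through the first ReLU unnormalized,
    #: so a nonlinear trace of it survives the later instance norms
    #: (which subtract anything constant along time).
    first_layer_norm: bool = True


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture hyperparameters of the 70x1 patch discriminator."""

    input_length: int = 256
    kernel: int = 4
    filters: tuple[int, ...] = (64, 128, 256, 512)
    strides: tuple[int, ...] = (2, 2, 2, 1)
    leaky_alpha: float = 0.2
    init_mean: float = 0.0
    init_sd: float = 0.02
    #: "channel" normalizes across channels per time step after every
    #: hidden convolution except the first — it rescales activations the
    #: way the reference PatchGAN's normalization does, but without the
    #: temporal coupling that would blur the patch receptive field.
    norm: str = "channel"

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(self.filters))
        object.__setattr__(self, "strides", tuple(self.strides))
        if len(self.filters) != len(self.strides):
            raise ValueError("filters and strides must align")

    @property
    def receptive_field(self) -> int:
        """Receptive field of one patch score, by stride arithmetic."""
        rf = 1
        for k, s in [(self.kernel, 1)] + list(
            zip(reversed((self.kernel,) * len(self.filters)),
                reversed(self.strides))
        ):
            rf = rf * s + (k - s)
        return rf


def _init_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int,
               mean: float, sd: float) -> tuple[Parameter, Parameter]:
    w = Parameter(rng.normal(mean, sd, size=(c_out, c_in, k)))
    b = Parameter(np.zeros(c_out))
    return w, b


class _ConvNet:
    """Shared plumbing: parameter registry and condition tiling."""

    def __init__(self, n_classes: int):
        if n_classes < 2:
            raise ValueError("conditioning requires at least 2 classes")
        self.n_classes = n_classes
        self.params: list[Parameter] = []

    def _register(self, wb: tuple[Parameter, Parameter]):
        self.params.extend(wb)
        return wb

    def _tile_condition(self, onehot: np.ndarray, length: int) -> np.ndarray:
        onehot = np.atleast_2d(np.asarray(onehot, dtype=np.float64))
        if onehot.shape[1] != self.n_classes:
            raise ValueError(
                f"expected one-hot of length {self.n_classes}, got {onehot.shape[1]}"
            )
        return np.repeat(onehot[:, :, None], length, axis=2)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_state(self, state) -> None:
        for p, s in zip(self.params, state, strict=True):
            p.data = np.array(s, dtype=np.float64, copy=True)


class Generator(_ConvNet):
    """Class-conditioned signal-to-signal generator G(x, z) -> y."""

    def __init__(self, spec: GeneratorSpec, n_classes: int, seed: int = 0):
        super().__init__(n_classes)
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, ek, ik = spec.base_filters, spec.edge_kernel, spec.inner_kernel
        init = (spec.init_mean, spec.init_sd)

        self.enc_in = self._register(_init_conv(rng, f, 1 + n_classes, ek, *init))
        self.down = []
        c = f
        for _ in range(spec.n_downsample):
            self.down.append(self._register(_init_conv(rng, c * 2, c, ik, *init)))
            c *= 2
        self.res = []
        for _ in range(spec.n_resnet_blocks):
            self.res.append((
                self._register(_init_conv(rng, c, c, ik, *init)),
                self._register(_init_conv(rng, c, c, ik, *init)),
            ))
        self.up = []
        for _ in range(spec.n_downsample):
            self.up.append(self._register(_init_conv(rng, c // 2, c, ik, *init)))
            c //= 2
        self.dec_out = self._register(
            _init_conv(rng, spec.output_channels, c, ek, *init))

    def _norm(self, h: Tensor) -> Tensor:
        if self.spec.norm == "channel":
            return ad.channel_norm(h)
        if self.spec.norm == "instance":
            return ad.instance_norm(h)
        return h

    def forward(self, x: Tensor, onehot: np.ndarray) -> Tensor:
        """x: Tensor (N, 1, L); onehot: (N, K). Returns Tensor (N, 1, L)."""
        length = x.data.shape[2]
        h = ad.concat_condition(x, self._tile_condition(onehot, length))
        h = ad.conv1d(h, *self.enc_in, stride=1)
        h = ad.relu(self._norm(h) if self.spec.first_layer_norm else h)
        for w, b in self.down:
            h = ad.relu(self._norm(ad.conv1d(h, w, b, stride=2)))
        for (w1, b1), (w2, b2) in self.res:
            r = ad.relu(self._norm(ad.conv1d(h, w1, b1, stride=1)))
            r = self._norm(ad.conv1d(r, w2, b2, stride=1))
            h = ad.add(h, r)
        for w, b in self.up:
            h = ad.upsample_nearest(h, 2)
            h = ad.relu(self._norm(ad.conv1d(h, w, b, stride=1)))
        h = ad.conv1d(h, *self.dec_out, stride=1)
        if self.spec.output_activation == "sigmoid":
            h = ad.sigmoid(h)
        return h

    def __call__(self, x: np.ndarray, onehot: np.ndarray) -> np.ndarray:
        """Inference on plain arrays: (N, 256) + (N, K) -> (N, 256)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        with ad.no_grad():
            out = self.forward(Tensor(x[:, None, :]), onehot)
        return out.data[:, 0, :]


class Discriminator(_ConvNet):
    """Class-conditioned PatchGAN D(x, z) -> patch score map (logits)."""

    def __init__(self, spec: DiscriminatorSpec, n_classes: int, seed: int = 0):
        super().__init__(n_classes)
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.kernel
        init = (spec.init_mean, spec.init_sd)
        self.layers = []
        c = 1 + n_classes
        for f_out, s in zip(spec.filters, spec.strides):
            self.layers.append(
                (self._register(_init_conv(rng, f_out, c, k, *init)), s))
            c = f_out
        self.out = self._register(_init_conv(rng, 1, c, k, *init))

    def forward(self, x: Tensor, onehot: np.ndarray) -> Tensor:
        """x: Tensor (N, 1, L); returns patch logits (N, 1, L_patches)."""
        length = x.data.shape[2]
        h = ad.concat_condition(x, self._tile_condition(onehot, length))
        for i, ((w, b), s) in enumerate(self.layers):
            h = ad.conv1d(h, w, b, stride=s)
            if i > 0 and self.spec.norm == "channel":
                h = ad.channel_norm(h)
            h = ad.leaky_relu(h, self.spec.leaky_alpha)
        return ad.conv1d(h, *self.out, stride=1)

    def __call__(self, x: np.ndarray, onehot: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        with ad.no_grad():
            out = self.forward(Tensor(x[:, None, :]), onehot)
        return out.data[:, 0, :]


def build_generator(spec: GeneratorSpec, n_classes: int, seed: int = 0) -> Generator:
    """Construct a freshly initialized conditional generator."""
    return Generator(spec, n_classes, seed)


def build_discriminator(spec: DiscriminatorSpec, n_classes: int,
                        seed: int = 0) -> Discriminator:
    """Construct a freshly initialized conditional patch discriminator."""
    return Discriminator(spec, n_classes, seed)
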