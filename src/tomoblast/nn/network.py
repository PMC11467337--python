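"""The 3D tail-body-head classifier at configurable scale.

The network is a multi-resolution encoder/decoder/re-encoder: the *tail*
extracts features while max-pool downsampling, the *body* upsamples with
nearest-neighbour resizing and, after every upsampling step, concatenates the
first feature maps the tail produced at that resolution (equal-sampling
feature recollection), and the *head* downsamples again.  A residual
bottleneck block precedes every pooling or upsampling operation; every
convolution inside a block is preceded by instance normalization and
leaky-ReLU pre-activation.  Global average pooling feeds a latent projection
(the feature vector used for embedding analyses) and a two-way output layer
(wild-type vs mutant raw scores).

The published full-scale network (~8.1e7 parameters, 247 convolutional
layers at 160x160x72 input) fixes only the topology publicly, so channel
widths, stage counts and latent size are configuration here; the ``tiny``
preset trains on a CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (Conv3d, Dense, GlobalAvgPool, InstanceNorm, Layer,
                     LeakyReLU, MaxPool2, Upsample2)

__all__ = ["ArchConfig", "Bottleneck", "TomoNet", "build_network",
           "TINY_ARCH", "FULL_ARCH"]


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters.

    ``input_shape`` is (D, H, W) in array (z, y, x) order; all three spatial
    dims must be divisible by ``2**stages``.
    """

    input_shape: tuple[int, int, int] = (72, 160, 160)
    stages: int = 2              # pooling steps per component (tail/body/head)
    base_width: int = 8          # channels after the stem convolution
    reduction: int = 2           # bottleneck channel reduction factor
    latent_dim: int = 264
    leaky_slope: float = 0.1

    def validate(self) -> None:
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.base_width < 1 or self.reduction < 1:
            raise ValueError("base_width and reduction must be positive")
        f = 2 ** self.stages
        for d in self.input_shape:
            if d % f != 0 or d < f:
                raise ValueError(
                    f"input shape {self.input_shape} is not divisible by 2^stages={f}"
                )


#: Desk-scale preset used throughout the test suite.
TINY_ARCH = ArchConfig(input_shape=(16, 32, 32), stages=1, base_width=4,
                       reduction=2, latent_dim=32)

#: Topology preset at the published input size (reduced width; the exact
#: published channel plan is not public).
FULL_ARCH = ArchConfig(input_shape=(72, 160, 160), stages=3, base_width=16,
                        reduction=4, latent_dim=264)


class Bottleneck(Layer):
    """Pre-activation residual bottleneck.

    A shared InstanceNorm + leaky-ReLU pre-activation feeds two paths that
    are summed: a single 1x1x1 convolution, and a 1x1x1 -> 3x3x3 -> 1x1x1
    chain through ``c_out / reduction`` channels (each inner convolution with
    its own pre-activation).
    """

    def __init__(self, c_in: int, c_out: int, reduction: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        c_mid = max(1, c_out // reduction)
        self.pre_norm = InstanceNorm(c_in)
        self.pre_act = LeakyReLU(slope)
        self.skip = Conv3d(c_in, c_out, 1, rng)
        self.conv_in = Conv3d(c_in, c_mid, 1, rng)
        self.norm2 = InstanceNorm(c_mid)
        self.act2 = LeakyReLU(slope)
        self.conv_mid = Conv3d(c_mid, c_mid, 3, rng)
        self.norm3 = InstanceNorm(c_mid)
        self.act3 = LeakyReLU(slope)
        self.conv_out = Conv3d(c_mid, c_out, 1, rng)
        self.c_in, self.c_out = c_in, c_out

    @property
    def sublayers(self):
        return [self.pre_norm, self.pre_act, self.skip, self.conv_in, self.norm2,
                self.act2, self.conv_mid, self.norm3, self.act3, self.conv_out]

    @property
    def n_params(self):
        return sum(l.n_params for l in self.sublayers)

    def forward(self, x, training=True):
        pre = self.pre_act.forward(self.pre_norm.forward(x, training), training)
        s = self.skip.forward(pre, training)
        m = self.conv_in.forward(pre, training)
        m = self.conv_mid.forward(self.act2.forward(self.norm2.forward(m, training), training), training)
        m = self.conv_out.forward(self.act3.forward(self.norm3.forward(m, training), training), training)
        return s + m

    def backward(self, dy):
        dm = self.conv_out.backward(dy)
        dm = self.norm3.backward(self.act3.backward(dm))
        dm = self.conv_mid.backward(dm)
        dm = self.norm2.backward(self.act2.backward(dm))
        dpre = self.conv_in.backward(dm) + self.skip.backward(dy)
        return self.pre_norm.backward(self.pre_act.backward(dpre))


class TomoNet:
    """Forward/backward graph of the tail-body-head classifier."""

    def __init__(self, arch: ArchConfig, rng: np.random.Generator | int | None = None):
        arch.validate()
        self.arch = arch
        rng = np.random.default_rng(rng)
        s, w, r, slope = arch.stages, arch.base_width, arch.reduction, arch.leaky_slope

        self.stem = Conv3d(1, w, 3, rng, needs_input_grad=False)
        # channel plan: tail doubles per stage, body halves before each
        # upsample then gains the tail tap channels by concatenation,
        # head doubles per stage again
        self.tail_blocks, self.tail_pools = [], []
        tap_channels = []
        c = w
        for _ in range(s):
            tap_channels.append(c)
            blk = Bottleneck(c, 2 * c, r, slope, rng)
            self.tail_blocks.append(blk)
            self.tail_pools.append(MaxPool2())
            c = 2 * c
        self.body_blocks, self.body_ups = [], []
        for i in range(s):
            c_half = max(1, c // 2)
            blk = Bottleneck(c, c_half, r, slope, rng)
            self.body_blocks.append(blk)
            self.body_ups.append(Upsample2())
            c = c_half + tap_channels[s - 1 - i]
        self.head_blocks, self.head_pools = [], []
        for _ in range(s):
            blk = Bottleneck(c, 2 * c, r, slope, rng)
            self.head_blocks.append(blk)
            self.head_pools.append(MaxPool2())
            c = 2 * c
        # no normalization before pooling: instance norm zeroes each
        # channel's spatial mean, which would cancel in the global average
        self.gap = GlobalAvgPool()
        self.fc_latent = Dense(c, arch.latent_dim, rng)
        self.latent_act = LeakyReLU(slope)
        self.fc_out = Dense(arch.latent_dim, 2, rng)
        self._tap_channels = tap_channels
        self._split_channels = []  # upsampled-channel counts at each concat

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out = [self.stem]
        for blk in self.tail_blocks + self.body_blocks + self.head_blocks:
            out.extend(blk.sublayers)
        out += [self.fc_latent, self.fc_out]
        return [l for l in out if l.params]

    def parameter_count(self) -> int:
        return sum(l.n_params for l in self.layers)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": v for i, l in enumerate(self.layers)
                for k, v in l.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            for k in l.params:
                l.params[k] = np.array(state[f"{i}.{k}"], dtype=np.float32)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Raw two-class scores for a batch ``(N, 1, D, H, W)`` (or without
        the channel axis).  The latent vectors of the batch are cached on
        ``self.latent``."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.arch.input_shape):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != configured {self.arch.input_shape}"
            )
        s = self.arch.stages
        x = self.stem.forward(x, training)
        taps = []
        for blk, pool in zip(self.tail_blocks, self.tail_pools):
            taps.append(x)
            x = pool.forward(blk.forward(x, training), training)
        self._split_channels = []
        for i, (blk, up) in enumerate(zip(self.body_blocks, self.body_ups)):
            x = up.forward(blk.forward(x, training), training)
            self._split_channels.append(x.shape[1])
            x = np.concatenate([x, taps[s - 1 - i]], axis=1)
        for blk, pool in zip(self.head_blocks, self.head_pools):
            x = pool.forward(blk.forward(x, training), training)
        pooled = self.gap.forward(x, training)
        latent = self.fc_latent.forward(pooled, training)
        self.latent = latent.copy()
        out = self.fc_out.forward(self.latent_act.forward(latent, training), training)
        return out

    def backward(self, dout: np.ndarray) -> None:
        s = self.arch.stages
        d = self.fc_out.backward(dout)
        d = self.fc_latent.backward(self.latent_act.backward(d))
        d = self.gap.backward(d)
        for blk, pool in zip(reversed(self.head_blocks), reversed(self.head_pools)):
            d = blk.backward(pool.backward(d))
        dtaps: dict[int, np.ndarray] = {}
        for i in range(s - 1, -1, -1):
            c_up = self._split_channels[i]
            dtaps[s - 1 - i] = d[:, c_up:]
            d = self.body_blocks[i].backward(self.body_ups[i].backward(d[:, :c_up]))
        for i in range(s - 1, -1, -1):
            d = self.tail_blocks[i].backward(self.tail_pools[i].backward(d))
            d = d + dtaps[i]
        self.stem.backward(d)

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()


def build_network(arch: ArchConfig, rng=None) -> tuple[TomoNet, int]:
    """Construct the network; returns ``(model, parameter_count)``.

    Invalid configurations (spatial dims not divisible by ``2**stages``)
    raise before any array allocation.
    """
    arch.validate()
    model = TomoNet(arch, rng)
    return model, model.parameter_count()
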