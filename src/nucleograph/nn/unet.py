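"""The 3-D U-Net used for density segmentation.

Encoder: ``depth`` downsampling blocks, each two convolutional blocks
(conv -> instance norm -> ReLU) followed by 2x2x2 max pooling; the first
block raises the channel count from 1 to ``first_filters`` and every later
block doubles it while pooling halves each spatial edge.  Bottleneck: two
convolutional blocks *without* normalisation (the deep representation is a
(1,1,1,512)-shaped vector at default settings and whitening it per sample
would destroy it).  Decoder: ``depth`` upsampling blocks — transposed
convolution doubling the spatial edges and halving the channels,
concatenation with the matching encoder skip, then two convolutional
blocks.  Head: 1x1x1 convolution to two channels with a softmax pairing
"within 1.5 Å of the target group" against "not".
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import (Conv3d, ConvTranspose3d, InstanceNorm3d, Layer,
                     MaxPool3d, Param, ReLU, softmax_channels)


@dataclass
class UNetConfig:
    input_edge: int = 32
    input_channels: int = 1
    first_filters: int = 16
    depth: int = 5
    output_channels: int = 2
    conv_kernel: int = 3
    pool_size: int = 2
    norm: str = "instance"
    # prior probability of the positive class used to initialise the head
    # bias (the focal-loss recipe: rare-class heads start near the prior
    # instead of 0.5, which stabilises early training)
    head_prior: float = 0.05

    def __post_init__(self) -> None:
        if self.input_edge % (self.pool_size ** self.depth) != 0:
            raise ValueError(
                f"input_edge {self.input_edge} not divisible by "
                f"pool_size^depth = {self.pool_size ** self.depth}")
        if self.output_channels < 2:
            raise ValueError("output_channels must be >= 2")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")
        if not (0.0 < self.head_prior < 1.0):
            raise ValueError("head_prior must be in (0, 1)")


@dataclass
class ShapeTrace:
    """Per-stage (spatial_edge, filter_count) bookkeeping of the network."""

    encoder: list[tuple[int, int]]     # input + after each down block
    bottleneck: tuple[int, int]
    decoder: list[tuple[int, int]]     # after each up block
    head: tuple[int, int]

    @property
    def first_block_filters(self) -> int:
        return self.encoder[1][1]

    @property
    def bottleneck_filters(self) -> int:
        return self.bottleneck[1]

    @property
    def decoder_block_count(self) -> int:
        return len(self.decoder)

    @property
    def output_channels(self) -> int:
        return self.head[1]


def trace_shapes(cfg: UNetConfig) -> ShapeTrace:
    edge, filters = cfg.input_edge, cfg.input_channels
    encoder = [(edge, filters)]
    filters = cfg.first_filters
    for _ in range(cfg.depth):
        edge //= cfg.pool_size
        encoder.append((edge, filters))
        filters *= 2
    filters //= 2
    bottleneck = (edge, filters * 2)
    decoder = []
    for _ in range(cfg.depth):
        edge *= cfg.pool_size
        decoder.append((edge, filters))
        filters //= 2
    head = (cfg.input_edge, cfg.output_channels)
    return ShapeTrace(encoder=encoder, bottleneck=bottleneck,
                      decoder=decoder, head=head)


class ConvBlock(Layer):
    """conv -> (instance norm) -> ReLU."""

    def __init__(self, cin: int, cout: int, kernel: int, normalize: bool,
                 rng: np.random.Generator, dtype=np.float32):
        self.layers: list[Layer] = [Conv3d(cin, cout, kernel, rng, dtype)]
        if normalize:
            self.layers.append(InstanceNorm3d(cout, dtype=dtype))
        self.layers.append(ReLU())

    def params(self) -> list[Param]:
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


class DownBlock(Layer):
    """Two conv blocks then max pooling; keeps the pre-pool skip tensor."""

    def __init__(self, cin: int, cout: int, cfg: UNetConfig,
                 rng: np.random.Generator, dtype=np.float32):
        normalize = cfg.norm == "instance"
        self.conv1 = ConvBlock(cin, cout, cfg.conv_kernel, normalize, rng,
                               dtype)
        self.conv2 = ConvBlock(cout, cout, cfg.conv_kernel, normalize, rng,
                               dtype)
        self.pool = MaxPool3d(cfg.pool_size)
        self.skip: np.ndarray | None = None

    def params(self) -> list[Param]:
        return self.conv1.params() + self.conv2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.conv2.forward(self.conv1.forward(x))
        self.skip = x
        return self.pool.forward(x)

    def backward(self, dout: np.ndarray,
                 dskip: np.ndarray | None = None) -> np.ndarray:
        dx = self.pool.backward(dout)
        if dskip is not None:
            dx = dx + dskip
        self.skip = None
        return self.conv1.backward(self.conv2.backward(dx))


class UpBlock(Layer):
    """Transposed conv, skip concatenation, two conv blocks."""

    def __init__(self, cin: int, cout: int, cfg: UNetConfig,
                 rng: np.random.Generator, dtype=np.float32):
        normalize = cfg.norm == "instance"
        self.tconv = ConvTranspose3d(cin, cout, cfg.pool_size, rng, dtype)
        self.conv1 = ConvBlock(2 * cout, cout, cfg.conv_kernel, normalize,
                               rng, dtype)
        self.conv2 = ConvBlock(cout, cout, cfg.conv_kernel, normalize, rng,
                               dtype)
        self._skip_channels = cout

    def params(self) -> list[Param]:
        return (self.tconv.params() + self.conv1.params()
                + self.conv2.params())

    def forward(self, x: np.ndarray, skip: np.ndarray) -> np.ndarray:
        up = self.tconv.forward(x)
        cat = np.concatenate([skip, up], axis=1)
        return self.conv2.forward(self.conv1.forward(cat))

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dcat = self.conv1.backward(self.conv2.backward(dout))
        c = self._skip_channels
        dskip, dup = dcat[:, :c], dcat[:, c:]
        dx = self.tconv.backward(dup)
        return dx, dskip


class UNet3D:
    """Full encoder-decoder network with seedable initialisation."""

    def __init__(self, config: UNetConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.config = config or UNetConfig()
        self.dtype = dtype
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.down_blocks: list[DownBlock] = []
        cin = cfg.input_channels
        cout = cfg.first_filters
        for _ in range(cfg.depth):
            self.down_blocks.append(DownBlock(cin, cout, cfg, rng, dtype))
            cin, cout = cout, cout * 2
        # bottleneck: two conv blocks, no normalisation
        bott = cin * 2
        self.bottleneck = [
            ConvBlock(cin, bott, cfg.conv_kernel, False, rng, dtype),
            ConvBlock(bott, bott, cfg.conv_kernel, False, rng, dtype),
        ]
        self.up_blocks: list[UpBlock] = []
        cin = bott
        for _ in range(cfg.depth):
            self.up_blocks.append(UpBlock(cin, cin // 2, cfg, rng, dtype))
            cin //= 2
        self.head = Conv3d(cin, cfg.output_channels, 1, rng, dtype)
        # focal-loss prior initialisation: the positive channel starts at
        # the class prior rather than 0.5
        pi = cfg.head_prior
        self.head.b.value[1] = np.log(pi / (1.0 - pi))

    # -- plumbing ---------------------------------------------------------

    def parameters(self) -> list[Param]:
        ps: list[Param] = []
        for blk in self.down_blocks:
            ps += blk.params()
        for blk in self.bottleneck:
            ps += blk.params()
        for blk in self.up_blocks:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def shape_trace(self) -> ShapeTrace:
        return trace_shapes(self.config)

    # -- forward / backward ----------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, e, e, e) input -> (N, 2, e, e, e) logits."""
        if np.isnan(x).any():
            raise ValueError("input contains NaN")
        x = x.astype(self.dtype, copy=False)
        skips = []
        for blk in self.down_blocks:
            x = blk.forward(x)
            skips.append(blk.skip)
        for blk in self.bottleneck:
            x = blk.forward(x)
        for blk, skip in zip(self.up_blocks, reversed(skips)):
            x = blk.forward(x, skip)
        return self.head.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities, channel pair summing to 1 per voxel."""
        return softmax_channels(self.forward_logits(x))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits.astype(self.dtype, copy=False))
        dskips: list[np.ndarray] = []
        for blk in reversed(self.up_blocks):
            d, dskip = blk.backward(d)
            dskips.append(dskip)
        for blk in reversed(self.bottleneck):
            d = blk.backward(d)
        # dskips were appended shallow-first, matching down_blocks order
        for blk, dskip in zip(reversed(self.down_blocks),
                              reversed(dskips)):
            d = blk.backward(d, dskip)

    # -- inference adapter ------------------------------------------------

    def predict_proba(self, chunk_values: np.ndarray,
                      origins=None) -> np.ndarray:
        """Batch of cubes (B, e, e, e) -> channel-last (B, e, e, e, 2)."""
        x = np.asarray(chunk_values, dtype=self.dtype)[:, None]
        probs = self.forward(x)
        return np.moveaxis(probs, 1, -1)

    # -- serialisation ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with np.load(path, allow_pickle=False) as data:
            cfg = UNetConfig(**json.loads(str(data["__config__"])))
            net = cls(cfg)
            for i, p in enumerate(net.parameters()):
                stored = data[f"p{i}"]
                if stored.shape != p.value.shape:
                    raise ValueError(
                        f"weight {i} shape {stored.shape} does not match "
                        f"the configured architecture {p.value.shape}")
                p.value[...] = stored
        return net


def build_network(cfg: UNetConfig | None = None,
                  seed: int = 0) -> tuple[UNet3D, ShapeTrace]:
    """Construct the network and report its shape progression."""
    cfg = cfg or UNetConfig()
    return UNet3D(cfg, seed=seed), trace_shapes(cfg)
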