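"""MSFA-U-Net: a U-Net with HRNet-style parallel multi-resolution branches,
repeated cross-scale feature fusion, and channel squeeze-and-excitation (cSE)
attention residual blocks.

Architecture summary
--------------------
Encoder: stage ``k`` (k = 0..L-1) holds branches 0..k at resolutions
``full / 2^i``; entering stage k spawns branch k from branch k-1 with a
stride-2 convolution, every active branch runs an attention residual block,
and the branches then exchange information through a multi-scale fusion
(elementwise sum of identity / stride-conv / transposed-conv transitions).

Decoder: classic U-Net merge-up — transposed convolution, concatenation with
the (post-fusion) encoder feature of that level, dropout after the skip
concatenation, then an attention residual block in place of the usual pair of
convolutions.  A final 1x1 convolution with a sigmoid produces the per-pixel
foreground probability.

The attention residual block is
``cSE(ReLU(BN(conv3x3(ReLU(BN(conv3x3(x))))))) + BN(conv1x1(x))`` and the cSE
gate is ``sigmoid(W2 @ ReLU(W1 @ GAP(x)))`` with ``W1`` halving the channel
count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autodiff as ad
from .nn import BatchNorm2d, Conv2d, ConvTranspose2d, Dense, Dropout, Module, Tensor


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    num_levels is the number of resolution branches; branch ``i`` runs at
    ``full_resolution / 2**i`` with ``base_channels * 2**i`` channels.
    Inputs must have spatial dimensions divisible by ``2**(num_levels - 1)``.
    """

    in_channels: int = 1
    num_levels: int = 4
    base_channels: int = 32
    cse_reduction: int = 2
    dropout_rate: float = 0.2
    out_channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.num_levels < 2:
            errors.append(f"num_levels must be >= 2, got {self.num_levels}")
        if self.base_channels % 2 != 0 or self.base_channels < self.cse_reduction:
            errors.append(
                f"base_channels must be even and >= cse_reduction "
                f"({self.cse_reduction}), got {self.base_channels}")
        if not 0.0 <= self.dropout_rate < 1.0:
            errors.append(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if errors:
            raise ValueError("invalid ModelConfig: " + "; ".join(errors))

    @property
    def widths(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.num_levels)]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


class CSEBlock(Module):
    """Channel squeeze-and-excitation: GAP -> Dense(C -> C/r) -> ReLU ->
    Dense(C/r -> C) -> sigmoid -> channelwise rescale."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        hidden = max(channels // reduction, 1)
        self.squeeze = Dense(channels, hidden, rng)
        self.excite = Dense(hidden, channels, rng)

    def gate(self, fm: Tensor) -> Tensor:
        z = ad.global_avg_pool(fm)
        return ad.sigmoid(self.excite(ad.relu(self.squeeze(z))))

    def forward(self, fm: Tensor) -> Tensor:
        if fm.data.shape[1] != self.channels:
            raise ValueError(
                f"cSE expects {self.channels} channels, got {fm.data.shape[1]}")
        return ad.channel_gate(fm, self.gate(fm))


def cse_recalibrate(fm: Tensor, block: CSEBlock) -> Tensor:
    """Functional alias: recalibrate `fm` with the given cSE block's weights."""
    return block(fm)


class AttentionResBlock(Module):
    """Two 3x3 conv-BN-ReLU stages ending in a cSE gate, plus a projection
    shortcut (1x1 conv + BN); preserves spatial dimensions."""

    def __init__(self, in_ch: int, out_ch: int, cse_reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, 1, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.cse = CSEBlock(out_ch, cse_reduction, rng)
        self.proj = Conv2d(in_ch, out_ch, 1, 1, rng)
        self.bn_proj = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        h = ad.relu(self.bn2(self.conv2(h)))
        h = self.cse(h)
        return ad.add(h, self.bn_proj(self.proj(x)))


class DownscaleTransition(Module):
    """`levels_down` chained 3x3 stride-2 convolutions; halves H and W each."""

    def __init__(self, in_ch: int, out_ch: int, levels_down: int,
                 rng: np.random.Generator):
        super().__init__()
        if levels_down < 1:
            raise ValueError("levels_down must be >= 1 (use identity for 0)")
        self.convs = [
            Conv2d(in_ch if i == 0 else out_ch, out_ch, 3, 2, rng)
            for i in range(levels_down)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            _, _, H, W = x.data.shape
            if H % 2 or W % 2:
                raise ValueError(f"spatial dims {(H, W)} not divisible by 2")
            x = conv(x)
        return x


class UpscaleTransition(Module):
    """`levels_up` chained 3x3 stride-2 transposed convolutions; doubles H, W."""

    def __init__(self, in_ch: int, out_ch: int, levels_up: int,
                 rng: np.random.Generator):
        super().__init__()
        if levels_up < 1:
            raise ValueError("levels_up must be >= 1 (use identity for 0)")
        self.convs = [
            ConvTranspose2d(in_ch if i == 0 else out_ch, out_ch, rng)
            for i in range(levels_up)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x)
        return x


class MultiScaleFuse(Module):
    """Cross-scale fusion: output for branch i is the elementwise sum over all
    branches j of a transition from j's resolution to i's (identity if j == i,
    stride convolutions if j < i, transposed convolutions if j > i)."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        super().__init__()
        self.widths = widths
        n = len(widths)
        self.transitions = []
        for i in range(n):
            row = []
            for j in range(n):
                if j == i:
                    row.append(None)
                elif j < i:
                    row.append(DownscaleTransition(widths[j], widths[i], i - j, rng))
                else:
                    row.append(UpscaleTransition(widths[j], widths[i], j - i, rng))
            self.transitions.append(row)

    def modules(self):
        yield self
        for row in self.transitions:
            for t in row:
                if t is not None:
                    yield from t.modules()

    def named_parameters(self, prefix: str = ""):
        for i, row in enumerate(self.transitions):
            for j, t in enumerate(row):
                if t is not None:
                    sub = f"{prefix}.t{i}_{j}" if prefix else f"t{i}_{j}"
                    yield from t.named_parameters(sub)

    def forward(self, branch_fms: list[Tensor]) -> list[Tensor]:
        n = len(branch_fms)
        if n != len(self.widths):
            raise ValueError(f"expected {len(self.widths)} branches, got {n}")
        outs = []
        for i in range(n):
            acc = branch_fms[i]
            for j in range(n):
                if j != i:
                    acc = ad.add(acc, self.transitions[i][j](branch_fms[j]))
            outs.append(acc)
        return outs


class MSFAUNet(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.num_levels
        w = config.widths
        r = config.cse_reduction

        # encoder: stage k adds branch k then runs a block on every branch
        self.spawn = [DownscaleTransition(w[k - 1], w[k], 1, rng) for k in range(1, L)]
        self.enc_blocks = [
            [AttentionResBlock(config.in_channels if i == 0 and k == 0 else w[i],
                               w[i], r, rng)
             for i in range(k + 1)]
            for k in range(L)
        ]
        self.fuses = [MultiScaleFuse(w[:k + 1], rng) for k in range(1, L)]

        # decoder: merge up with transposed conv + skip concat + block
        self.ups = [ConvTranspose2d(w[i + 1], w[i], rng) for i in range(L - 1)]
        self.dec_blocks = [AttentionResBlock(2 * w[i], w[i], r, rng)
                           for i in range(L - 1)]
        self.dropouts = [Dropout(config.dropout_rate, seed=config.seed + 1000 + i)
                         for i in range(L - 1)]
        self.head = Conv2d(w[0], config.out_channels, 1, 1, rng)

    def named_parameters(self, prefix: str = ""):
        groups = [("spawn", self.spawn), ("fuse", self.fuses), ("up", self.ups),
                  ("dec", self.dec_blocks), ("head", [self.head])]
        for k, blocks in enumerate(self.enc_blocks):
            for i, b in enumerate(blocks):
                yield from b.named_parameters(f"enc{k}_{i}")
        for tag, mods in groups:
            for i, m in enumerate(mods):
                yield from m.named_parameters(f"{tag}{i}")

    def modules(self):
        yield self
        for blocks in self.enc_blocks:
            for b in blocks:
                yield from b.modules()
        for mods in (self.spawn, self.fuses, self.ups, self.dec_blocks,
                     self.dropouts, [self.head]):
            for m in mods:
                yield from m.modules()

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        N, C, H, W = x.data.shape
        L = self.config.num_levels
        div = 2 ** (L - 1)
        if H % div or W % div:
            raise ValueError(
                f"input spatial dims {(H, W)} must be divisible by {div} "
                f"for num_levels={L}")
        branches = [self.enc_blocks[0][0](x)]
        for k in range(1, L):
            branches.append(self.spawn[k - 1](branches[-1]))
            branches = [self.enc_blocks[k][i](b) for i, b in enumerate(branches)]
            branches = self.fuses[k - 1](branches)
        d = branches[-1]
        for i in range(L - 2, -1, -1):
            d = self.ups[i](d)
            d = ad.concat_channels([d, branches[i]])
            d = self.dropouts[i](d)
            d = self.dec_blocks[i](d)
        return ad.sigmoid(self.head(d))


def build_model(config: ModelConfig) -> MSFAUNet:
    """Construct an MSFA-U-Net from a validated configuration."""
    return MSFAUNet(config)


def count_parameters(model: Module) -> int:
    return sum(p.data.size for p in model.parameters())
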