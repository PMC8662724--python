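"""MAFF-ResUNet: residual U-Net with a multi-scale attention feature fusion head.

The network is a 2D encoder-decoder over 4-channel multimodal MRI slices:

* Down path — four residual encoder blocks (two 3×3 conv + BN + ReLU with an
  additive shortcut, then 2×2 max-pool) plus a residual intermediate layer
  without pooling: five residual blocks in total. Channels double per level
  (base_filters · 2^level).
* Up path — four decoder blocks: 2× bilinear up-sampling, concatenation
  with the same-level encoder features (skip connection), two 3×3 conv +
  BN + ReLU.
* MAFF head — the four decoder outputs are projected to ``fusion_channels``
  (C) by 1×1 conv + BN + ReLU and bilinearly resampled to input resolution,
  giving pyramid levels F_1..F_4 (deepest first) and their channel
  concatenation F_m (4C channels). Per level an attention feature block
  (AFB) computes an attention map A_i from F_i and a 1×1-reduced F_m via a
  conv3×3/avg-pool2×/conv3×3/avg-pool2×/conv1×1 stack (BN + PReLU after
  each conv), 4× bilinear up-sampling, and a channelwise softmax. A_i
  re-weights F_m (broadcast over the four C-channel groups), the attended
  map is concatenated with F_i and refined by a 3×3 conv back to C
  channels. A per-level 1×1 conv maps each refined map to class logits; the
  four logit maps are averaged and passed through a sigmoid, giving
  independent WT/TC/ET probabilities.

The softmax normalization axis and the channel widths are configurable
defaults, not uniquely determined by the architecture description; see the
methods note for the reasoning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import (Tensor, avg_pool2, bilinear_resize, concat, max_pool2,
                       softmax)
from .nn import BatchNorm2d, Conv2d, Module, PReLU


@dataclass
class ModelConfig:
    in_channels: int = 4
    n_classes: int = 3
    base_filters: int = 32
    depth: int = 4
    fusion_channels: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.depth != 4:
            raise ValueError("this architecture is defined for depth 4")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        return cls(**json.loads(Path(path).read_text()))


class ResidualConvBlock(Module):
    """Two 3×3 conv + BN + ReLU with an additive shortcut.

    out = ReLU(BN(conv(ReLU(BN(conv(x))))) + shortcut(x)); the shortcut is a
    1×1 projection conv when channel counts differ, identity otherwise.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.shortcut = (Conv2d(in_channels, out_channels, 1, rng)
                         if in_channels != out_channels else None)

    def shortcut_path(self, x: Tensor) -> Tensor:
        return self.shortcut(x) if self.shortcut is not None else x

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + self.shortcut_path(x)).relu()


class EncoderBlock(Module):
    """Residual block followed by 2×2 max-pooling (halves spatial dims)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        self.block = ResidualConvBlock(in_channels, out_channels, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        features = self.block(x)
        return features, max_pool2(features)


class DecoderBlock(Module):
    """2× bilinear up-sample, concat with skip, two 3×3 conv + BN + ReLU."""

    def __init__(self, in_channels: int, skip_channels: int,
                 out_channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels + skip_channels, out_channels, 3, rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = BatchNorm2d(out_channels)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = bilinear_resize(x, skip.shape[2], skip.shape[3])
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(f"decoder spatial mismatch: {up.shape[2:]} vs "
                             f"skip {skip.shape[2:]}")
        h = concat([up, skip], axis=1)
        h = self.bn1(self.conv1(h)).relu()
        return self.bn2(self.conv2(h)).relu()


class ConvBNReLU(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        self.conv = Conv2d(in_channels, out_channels, kernel, rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class ConvBNPReLU(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        self.conv = Conv2d(in_channels, out_channels, kernel, rng)
        self.bn = BatchNorm2d(out_channels)
        self.act = PReLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class AttentionFeatureBlock(Module):
    """AFB: attention map A_i from a pyramid level F_i and the hybrid F_m.

    A_i = softmax(up_4x(g(concat(F_i, reduce_1x1(F_m))))) where g is
    conv3×3 → avg-pool2× → conv3×3 → avg-pool2× → conv1×1 with BN + PReLU
    after each convolution. The softmax normalizes across the C attention
    channels at each spatial location, so A_i ∈ (0,1) sums to 1 over
    channels.
    """

    def __init__(self, fusion_channels: int, rng: np.random.Generator):
        c = fusion_channels
        self.reduce = ConvBNReLU(4 * c, c, 1, rng)
        self.g1 = ConvBNPReLU(2 * c, c, 3, rng)
        self.g2 = ConvBNPReLU(c, c, 3, rng)
        self.g3 = ConvBNPReLU(c, c, 1, rng)

    def forward(self, f_i: Tensor, f_m: Tensor) -> Tensor:
        if f_i.shape[2:] != f_m.shape[2:]:
            raise ValueError(f"AFB spatial mismatch: F_i {f_i.shape[2:]} vs "
                             f"F_m {f_m.shape[2:]}")
        h, w = f_i.shape[2], f_i.shape[3]
        if h % 4 or w % 4:
            raise ValueError(f"AFB needs spatial dims divisible by 4, got "
                             f"{h}x{w}")
        x = concat([f_i, self.reduce(f_m)], axis=1)
        x = avg_pool2(self.g1(x))
        x = avg_pool2(self.g2(x))
        x = self.g3(x)
        x = bilinear_resize(x, h, w)
        return softmax(x, axis=1)


class MAFFResUNet(Module):
    """Full network: see module docstring for the dataflow."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_filters
        c = cfg.fusion_channels

        self.encoders = [
            EncoderBlock(cfg.in_channels, b, rng),
            EncoderBlock(b, 2 * b, rng),
            EncoderBlock(2 * b, 4 * b, rng),
            EncoderBlock(4 * b, 8 * b, rng),
        ]
        self.intermediate = ResidualConvBlock(8 * b, 16 * b, rng)
        # decoder i consumes the previous decoder output and the skip from
        # the same-level encoder; deepest decoder first
        self.decoders = [
            DecoderBlock(16 * b, 8 * b, 8 * b, rng),
            DecoderBlock(8 * b, 4 * b, 4 * b, rng),
            DecoderBlock(4 * b, 2 * b, 2 * b, rng),
            DecoderBlock(2 * b, b, b, rng),
        ]
        self.projections = [
            ConvBNReLU(8 * b, c, 1, rng),
            ConvBNReLU(4 * b, c, 1, rng),
            ConvBNReLU(2 * b, c, 1, rng),
            ConvBNReLU(b, c, 1, rng),
        ]
        self.afbs = [AttentionFeatureBlock(c, rng) for _ in range(4)]
        self.refiners = [ConvBNReLU(4 * c + c, c, 3, rng) for _ in range(4)]
        self.heads = [Conv2d(c, cfg.n_classes, 1, rng) for _ in range(4)]

    # -- stages, exposed for inspection and testing --------------------------
    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        skips = []
        h = x
        for enc in self.encoders:
            features, h = enc(h)
            skips.append(features)
        return skips, self.intermediate(h)

    def decode(self, bottleneck: Tensor, skips: list[Tensor]) -> list[Tensor]:
        outputs = []
        h = bottleneck
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = dec(h, skip)
            outputs.append(h)
        return outputs

    def build_pyramid(self, decoder_outputs: list[Tensor],
                      out_h: int, out_w: int) -> tuple[list[Tensor], Tensor]:
        """Project decoder outputs to C channels at input resolution.

        Returns (levels, hybrid) with levels ordered deepest first and
        hybrid the 4C-channel concatenation F_m.
        """
        levels = [
            bilinear_resize(proj(feat), out_h, out_w)
            for proj, feat in zip(self.projections, decoder_outputs)
        ]
        return levels, concat(levels, axis=1)

    def attend_and_refine(self, levels: list[Tensor], hybrid: Tensor
                          ) -> tuple[list[Tensor], list[Tensor]]:
        attention_maps = [afb(f_i, hybrid)
                          for afb, f_i in zip(self.afbs, levels)]
        refined = [self.refine_level(a_i, hybrid, f_i, refiner)
                   for a_i, f_i, refiner
                   in zip(attention_maps, levels, self.refiners)]
        return attention_maps, refined

    @staticmethod
    def apply_attention(a_i: Tensor, f_m: Tensor) -> Tensor:
        """Broadcast A_i (C channels) over F_m's four C-channel groups."""
        groups = f_m.shape[1] // a_i.shape[1]
        return concat([a_i] * groups, axis=1) * f_m

    def refine_level(self, a_i: Tensor, f_m: Tensor, f_i: Tensor,
                     refiner: Module) -> Tensor:
        attended = self.apply_attention(a_i, f_m)
        return refiner(concat([attended, f_i], axis=1))

    def fuse_head(self, refined: list[Tensor]) -> Tensor:
        """Per-level 1×1 class logits, averaged, then sigmoid."""
        logits = [head(f_r) for head, f_r in zip(self.heads, refined)]
        total = logits[0]
        for l in logits[1:]:
            total = total + l
        return (total * (1.0 / len(logits))).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError(f"expected a (N, C, H, W) batch, got shape "
                             f"{x.shape}")
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input "
                             f"channels, got {c}")
        if h % 16 or w % 16:
            raise ValueError(f"expected spatial dims divisible by 16, got "
                             f"{h}x{w}")
        skips, bottleneck = self.encode(x)
        decoder_outputs = self.decode(bottleneck, skips)
        levels, hybrid = self.build_pyramid(decoder_outputs, h, w)
        _, refined = self.attend_and_refine(levels, hybrid)
        return self.fuse_head(refined)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Serialize weights (+ running stats) and the config sidecar."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        meta = asdict(self.config)
        if extra:
            meta.update(extra)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MAFFResUNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig(**{k: meta[k] for k in
                                ModelConfig.__dataclass_fields__ if k in meta})
        model = cls(config)
        with np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz")) as state:
            model.load_state_dict(dict(state))
        return model

    def residual_blocks_in_down_path(self) -> list[ResidualConvBlock]:
        """The residual blocks of the down-sampling branch (should be 5)."""
        return [enc.block for enc in self.encoders] + [self.intermediate]
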