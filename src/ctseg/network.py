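"""Encoder-decoder 3D segmentation networks (UNet / VNet variants).

Both variants share the same skeleton: an encoder of *context modules*
(two convolution->dropout->instance-norm->leakyReLU blocks per level),
per-axis downsampling between levels, and a decoder of *localization
modules* fed by upsampled deep features concatenated with the skip
connection of the same level.  Feature counts start at ``base_features``
and double with every downsampling up to ``feature_cap``.

* **UNet** downsamples by max-pooling and upsamples by trilinear
  interpolation -- neither adds parameters.
* **VNet** is fully convolutional: strided convolutions on the way down,
  transposed convolutions on the way up.

Optional extensions, attached at build time:

* **attention gates** on the ``ag_levels`` topmost skip connections,
  suppressing skip features that the coarser decoder context deems
  irrelevant (see :mod:`ctseg.attention`);
* **deep supervision** heads on the ``dsv_levels`` topmost decoder
  levels, combined by an upsample-and-sum chain into the final score
  map (see :mod:`ctseg.supervision`).

Axes whose per-axis level budget is exhausted keep factor 1 at deeper
transitions, so anisotropic patches (e.g. 160x160x48 with budgets
5,5,3) remain valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import AttentionGate
from .nn import functional as F
from .nn.tensor import Tensor
from .supervision import DsvHead, combine_dsv

__all__ = ["NetworkSpec", "SegmentationNetwork", "build_network",
           "count_parameters", "validate_patch_size"]


@dataclass
class NetworkSpec:
    """Topology description; serialisable to/from plain dicts."""

    variant: str = "vnet"
    base_features: int = 30
    levels_per_axis: tuple[int, int, int] = (5, 5, 5)
    num_classes: int = 3
    in_channels: int = 1
    dropout_p: float = 0.1
    leaky_slope: float = 0.01
    feature_cap: int = 320
    ag_levels: int = 2
    dsv_levels: int = 3
    attention_f_int: int | None = None

    def __post_init__(self):
        self.levels_per_axis = tuple(int(v) for v in self.levels_per_axis)
        if self.variant not in ("unet", "vnet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.base_features < 1:
            raise ValueError("base_features must be >= 1")
        if len(self.levels_per_axis) != 3 or min(self.levels_per_axis) < 0:
            raise ValueError("levels_per_axis must be three counts >= 0")
        if max(self.levels_per_axis) > 5:
            raise ValueError("at most 5 downsamplings per axis")
        if max(self.levels_per_axis) < 1:
            raise ValueError("at least one axis must be downsampled")
        if not (0 <= self.ag_levels <= max(self.levels_per_axis)):
            raise ValueError("ag_levels out of range")
        if not (0 <= self.dsv_levels <= max(self.levels_per_axis)):
            raise ValueError("dsv_levels out of range")
        if self.dsv_levels and self.ag_levels > self.dsv_levels:
            raise ValueError("ag_levels must not exceed dsv_levels")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def n_transitions(self) -> int:
        return max(self.levels_per_axis)

    @property
    def features(self) -> list[int]:
        """Channel count per encoder level (doubling with cap)."""
        return [min(self.base_features * 2 ** l, self.feature_cap)
                for l in range(self.n_transitions + 1)]

    def factors(self, transition: int) -> tuple[int, int, int]:
        """Per-axis sampling factor for transition ``t`` (1-based)."""
        return tuple(2 if self.levels_per_axis[a] >= transition else 1
                     for a in range(3))

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "base_features": self.base_features,
            "levels_per_axis": list(self.levels_per_axis),
            "num_classes": self.num_classes, "in_channels": self.in_channels,
            "dropout_p": self.dropout_p, "leaky_slope": self.leaky_slope,
            "feature_cap": self.feature_cap, "ag_levels": self.ag_levels,
            "dsv_levels": self.dsv_levels,
            "attention_f_int": self.attention_f_int,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**{k: (tuple(v) if k == "levels_per_axis" else v)
                      for k, v in d.items()})


def validate_patch_size(spec: NetworkSpec, patch_size) -> None:
    """Raise if a patch cannot flow through the network; warn when the
    bottleneck feature maps fall below spatial size 8 (advisory only --
    the shipped per-task presets intentionally go below it)."""
    patch_size = tuple(int(v) for v in patch_size)
    for a in range(3):
        div = 2 ** spec.levels_per_axis[a]
        if patch_size[a] % div:
            raise ValueError(
                f"patch axis {a} ({patch_size[a]}) not divisible by "
                f"2^{spec.levels_per_axis[a]}")
    bottleneck = [patch_size[a] // 2 ** spec.levels_per_axis[a]
                  for a in range(3)]
    if min(bottleneck) < 8:
        warnings.warn(
            f"bottleneck feature maps have size {bottleneck}; the "
            "downsample-until-size-8 guideline is exceeded", stacklevel=2)


class _EncoderLevel(nn.Module):
    def __init__(self, spec: NetworkSpec, level: int, *,
                 rng: np.random.Generator):
        super().__init__()
        feats = spec.features
        self.level = level
        self.pool_factors = None
        kw = dict(dropout_p=spec.dropout_p, leaky_slope=spec.leaky_slope)
        if level == 0:
            in_ch = spec.in_channels
        else:
            f = spec.factors(level)
            if spec.variant == "vnet":
                self.down = nn.DownConv(feats[level - 1], feats[level], f,
                                        rng=rng)
                in_ch = feats[level]
            else:
                self.pool_factors = f
                in_ch = feats[level - 1]
        self.block1 = nn.ConvBlock(in_ch, feats[level], rng=rng, **kw)
        self.block2 = nn.ConvBlock(feats[level], feats[level], rng=rng, **kw)

    def forward(self, x: Tensor) -> Tensor:
        if self.level > 0:
            x = self.down(x) if self.pool_factors is None \
                else F.max_pool(x, self.pool_factors)
        return self.block2(self.block1(x))

    __call__ = forward


class _DecoderLevel(nn.Module):
    def __init__(self, spec: NetworkSpec, level: int, *,
                 rng: np.random.Generator):
        super().__init__()
        feats = spec.features
        self.level = level
        self.factors = spec.factors(level + 1)
        kw = dict(dropout_p=spec.dropout_p, leaky_slope=spec.leaky_slope)
        if spec.variant == "vnet":
            self.up = nn.UpConv(feats[level + 1], feats[level], self.factors,
                                rng=rng)
            cat_ch = 2 * feats[level]
        else:
            self.up = None  # trilinear interpolation, no parameters
            cat_ch = feats[level + 1] + feats[level]
        if level < spec.ag_levels:
            self.gate = AttentionGate(feats[level], feats[level + 1],
                                      self.factors,
                                      f_int=spec.attention_f_int, rng=rng)
        else:
            self.gate = None
        self.block1 = nn.ConvBlock(cat_ch, feats[level], rng=rng, **kw)
        self.block2 = nn.ConvBlock(feats[level], feats[level], rng=rng, **kw)
        if spec.dsv_levels and level < spec.dsv_levels:
            self.head = DsvHead(feats[level], spec.num_classes, level,
                                rng=rng)
        else:
            self.head = None


class SegmentationNetwork(nn.Module):
    """Built network; see module docstring for the topology."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        n = spec.n_transitions
        self.encoder = nn.ModuleList(
            _EncoderLevel(spec, l, rng=rng) for l in range(n + 1))
        self.decoder = nn.ModuleList(
            _DecoderLevel(spec, l, rng=rng) for l in range(n - 1, -1, -1))
        if spec.dsv_levels == 0:
            self.final_head = nn.Conv1x1(spec.features[0], spec.num_classes,
                                         rng=rng)
        else:
            self.final_head = None
        self.initialize(seed)

    # -- initialization ---------------------------------------------------
    def initialize(self, seed: int = 0) -> "SegmentationNetwork":
        """He-normal weights, zero biases, unit instance-norm gains,
        then pass-through re-initialization of every attention gate."""
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        for m in self.modules():
            if isinstance(m, nn.Conv3d):
                fan_in = int(np.prod(m.weight.data.shape[1:]))
            elif isinstance(m, nn.DownConv):
                fan_in = int(np.prod(m.weight.data.shape[1:]))
            elif isinstance(m, nn.UpConv):
                fan_in = int(m.weight.data.shape[0])
            elif isinstance(m, nn.Conv1x1):
                fan_in = int(m.weight.data.shape[1])
            else:
                continue
            m.weight.data = rng.normal(
                0.0, nn.he_fan_in_std(fan_in),
                m.weight.data.shape).astype(np.float32)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        for m in self.modules():
            if isinstance(m, nn.InstanceNorm3d):
                m.gamma.data = np.ones_like(m.gamma.data)
                m.beta.data = np.zeros_like(m.beta.data)
        for m in self.modules():
            if isinstance(m, AttentionGate):
                m.init_pass_through(rng)
        blocks = [m for m in self.modules() if isinstance(m, nn.ConvBlock)]
        for block, child in zip(blocks, ss.spawn(len(blocks))):
            block.set_dropout_rng(np.random.default_rng(child))
        return self

    # -- forward ----------------------------------------------------------
    def _check_input(self, arr: np.ndarray) -> None:
        if arr.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input "
                             f"channel(s), got {arr.shape[1]}")
        for a in range(3):
            div = 2 ** self.spec.levels_per_axis[a]
            if arr.shape[2 + a] % div:
                raise ValueError(
                    f"input axis {a} ({arr.shape[2 + a]}) not divisible "
                    f"by 2^{self.spec.levels_per_axis[a]}")

    def forward(self, x, mode: str = "eval", capture: bool = False):
        """Class scores for a (B, C, D, H, W) batch.

        ``mode='train'`` enables dropout; ``mode='eval'`` is
        deterministic.  With ``capture=True`` also returns a dict with
        the attention coefficient maps and secondary segmentation maps.
        """
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        if t.data.ndim != 5:
            raise ValueError("expected a 5D (B,C,D,H,W) input")
        self._check_input(t.data)
        self.train(mode == "train")

        skips: list[Tensor] = []
        h = t
        for level in self.encoder:
            h = level(h)
            if level.level < self.spec.n_transitions:
                skips.append(h)

        alphas: list[tuple[int, np.ndarray]] = []
        dsv_maps: list[Tensor] = []
        for dec in self.decoder:
            g = h
            if dec.up is not None:
                up = dec.up(h)
            else:
                up = F.upsample_linear(h, skips[dec.level].data.shape[2:])
            skip = skips[dec.level]
            if dec.gate is not None:
                skip, alpha = dec.gate(skip, g)
                alphas.append((dec.level, alpha.data))
            h = dec.block2(dec.block1(F.concat([up, skip])))
            if dec.head is not None:
                dsv_maps.append(dec.head(h))

        if self.final_head is not None:
            logits = self.final_head(h)
        else:
            logits = combine_dsv(dsv_maps)

        if capture:
            return logits, {"attention": alphas,
                            "dsv": [m.data for m in dsv_maps]}
        return logits

    __call__ = forward

    # -- inference convenience --------------------------------------------
    def predict_proba(self, patch: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (C, D, H, W) for one 3D patch."""
        logits = self.forward(patch[None, None], mode="eval")
        return F.softmax_channels(logits).data[0]


def build_network(spec: NetworkSpec, seed: int = 0) -> SegmentationNetwork:
    return SegmentationNetwork(spec, seed=seed)


def count_parameters(network: nn.Module) -> int:
    return network.count_parameters()
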