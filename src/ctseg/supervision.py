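"""Deep supervision: secondary segmentation heads and their sum chain.

Decoder features at the topmost levels are mapped to class scores by
1x1x1 convolutions ("secondary segmentation maps").  The coarsest map is
upsampled (trilinearly in 3D) to the next resolution, added to that
level's map, and the running sum keeps climbing until full resolution.
The loss is applied once to the combined output; the chain's role is to
shorten the gradient path to early decoder layers, not to refine the
final map.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["DsvHead", "combine_dsv"]


class DsvHead(nn.Module):
    """1x1x1 convolution producing class scores at one decoder level."""

    def __init__(self, in_ch: int, num_classes: int, level: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.level = level
        self.proj = nn.Conv1x1(in_ch, num_classes, rng=rng)

    def forward(self, features: Tensor) -> Tensor:
        return self.proj(features)

    __call__ = forward


def combine_dsv(maps: list[Tensor]) -> Tensor:
    """Upsample-and-sum a coarse-to-fine list of secondary score maps.

    Each successive map must be finer than its predecessor by a factor
    of 1 or 2 per axis (axes whose downsampling budget was exhausted
    stay at factor 1).  Returns scores at the finest map's resolution.
    """
    if not maps:
        raise ValueError("combine_dsv needs at least one map")
    s = maps[0]
    for nxt in maps[1:]:
        cur, fin = s.data.shape[2:], nxt.data.shape[2:]
        for a in range(3):
            if fin[a] % cur[a] or fin[a] // cur[a] not in (1, 2):
                raise ValueError(
                    f"incompatible shapes in supervision chain: {cur} -> {fin}")
        if s.data.shape[1] != nxt.data.shape[1]:
            raise ValueError("secondary maps disagree in class count")
        s = F.add(F.upsample_linear(s, fin), nxt)
    return s


def combine_dsv_arrays(maps: list[np.ndarray]) -> np.ndarray:
    """Array convenience wrapper around :func:`combine_dsv`."""
    ts = [Tensor(np.asarray(m)) for m in maps]
    return combine_dsv(ts).data
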