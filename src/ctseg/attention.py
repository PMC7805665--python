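"""Additive soft attention gates for skip connections.

A gate receives the skip-connection features ``x_l`` (fine grid, ``F_l``
channels) and a gating signal ``g`` taken from the next-coarser decoder
level (``F_g`` channels).  Both are mapped into an ``F_int``-dimensional
space with 1x1x1 convolutions -- the skip features are brought onto the
coarse grid by striding -- summed, rectified, projected to a scalar and
squashed with a sigmoid:

    q   = psi^T relu(W_x x↓ + W_g g + b_g) + b_psi
    a   = sigmoid(q)                       (coarse grid)
    α   = trilinear_upsample(a)            (fine grid, values in [0, 1])

The gated skip is the element-wise product ``x_l * α``, one coefficient
map shared across all channels.  Freshly initialized gates are
pass-through: the scalar projection starts at zero with a large positive
bias, so α ≈ 1 everywhere and the gate initially forwards every feature
vector unchanged while remaining fully trainable.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["AttentionGate", "attention_coefficients", "apply_gate",
           "init_pass_through", "PASS_THROUGH_BIAS"]

#: sigmoid(10) ≈ 0.99995, comfortably above the 0.99 pass-through bound
PASS_THROUGH_BIAS = 10.0


class AttentionGate(nn.Module):
    """Additive attention gate with shared-across-channels coefficients."""

    def __init__(self, f_l: int, f_g: int,
                 down_factors: tuple[int, int, int] = (2, 2, 2), *,
                 f_int: int | None = None, rng: np.random.Generator):
        super().__init__()
        if f_int is None:
            f_int = max(1, f_l // 2)
        self.f_l, self.f_g, self.f_int = f_l, f_g, f_int
        self.down_factors = tuple(down_factors)
        # W_x: no bias (the shared additive bias lives in W_g's b_g)
        self.theta_x = nn.Conv1x1(f_l, f_int, rng=rng, bias=False,
                                  stride=self.down_factors)
        self.phi_g = nn.Conv1x1(f_g, f_int, rng=rng, bias=True)
        self.psi = nn.Conv1x1(f_int, 1, rng=rng, bias=True)
        self.init_pass_through(rng)

    # -- initialization ---------------------------------------------------
    def init_pass_through(self, rng: np.random.Generator) -> None:
        """Re-initialize so the gate lets all feature vectors pass."""
        self.theta_x.weight.data = rng.normal(
            0.0, nn.he_fan_in_std(self.f_l),
            self.theta_x.weight.data.shape).astype(np.float32)
        self.phi_g.weight.data = rng.normal(
            0.0, nn.he_fan_in_std(self.f_g),
            self.phi_g.weight.data.shape).astype(np.float32)
        self.phi_g.bias.data = np.zeros_like(self.phi_g.bias.data)
        self.psi.weight.data = np.zeros_like(self.psi.weight.data)
        self.psi.bias.data = np.full_like(self.psi.bias.data,
                                          PASS_THROUGH_BIAS)

    # -- forward ----------------------------------------------------------
    def coefficients(self, x_l: Tensor, g: Tensor) -> Tensor:
        """Attention coefficient map α on the fine grid of ``x_l``."""
        if x_l.data.shape[1] != self.f_l or g.data.shape[1] != self.f_g:
            raise ValueError(
                f"channel mismatch: got x_l={x_l.data.shape[1]}, "
                f"g={g.data.shape[1]}, gate expects ({self.f_l}, {self.f_g})")
        coarse = tuple(x_l.data.shape[2 + a] // self.down_factors[a]
                       for a in range(3))
        if g.data.shape[2:] != coarse:
            raise ValueError(
                f"gating signal grid {g.data.shape[2:]} does not match the "
                f"strided skip grid {coarse}")
        q = F.relu(F.add(self.theta_x(x_l), self.phi_g(g)))
        a = F.sigmoid(self.psi(q))
        return F.upsample_linear(a, x_l.data.shape[2:])

    def forward(self, x_l: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        alpha = self.coefficients(x_l, g)
        return F.mul(x_l, alpha), alpha

    __call__ = forward


def attention_coefficients(x_l, g, gate: AttentionGate) -> np.ndarray:
    """Evaluate a gate's coefficient map on plain arrays.

    ``x_l`` and ``g`` may be numpy arrays shaped (C, D, H, W) or
    (B, C, D, H, W); the result mirrors the input layout with a single
    coefficient channel.
    """
    xa, ga = np.asarray(x_l, np.float32), np.asarray(g, np.float32)
    squeeze = xa.ndim == 4
    if squeeze:
        xa, ga = xa[None], ga[None]
    alpha = gate.coefficients(Tensor(xa), Tensor(ga)).data
    return alpha[0] if squeeze else alpha


def apply_gate(x_l: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Scale every channel of ``x_l`` by the shared coefficient map."""
    xa, aa = np.asarray(x_l), np.asarray(alpha)
    if xa.shape[-3:] != aa.shape[-3:]:
        raise ValueError(f"spatial shape mismatch: {xa.shape[-3:]} "
                         f"vs {aa.shape[-3:]}")
    return xa * aa


def init_pass_through(gate: AttentionGate,
                      rng: np.random.Generator) -> AttentionGate:
    gate.init_pass_through(rng)
    return gate
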