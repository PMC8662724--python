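"""Composite binary cross-entropy + soft Dice segmentation objective.

The total loss is Loss = α·BCE + β·Dice with defaults α = 0.5, β = 1 and
Dice smoothing ε = 1e-5. BCE handles per-pixel classification; the Dice
term handles region overlap. Both are computed per subregion channel
(WT, TC, ET) and averaged, weighting the three nested subregions equally.

Functions accept either :class:`~maffresunet.autodiff.Tensor` or plain
numpy arrays (wrapped as constants) and return a scalar Tensor, so the same
code is used for training (differentiable) and for standalone evaluation
(``.item()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

# predictions are clamped away from {0, 1} before the logs in BCE
PROB_CLIP = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.5      # weight on BCE
    beta: float = 1.0       # weight on Dice
    epsilon: float = 1e-5   # Dice smoothing

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(
                f"loss weights must be >= 0, got alpha={self.alpha}, "
                f"beta={self.beta}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _check_shapes(p: Tensor, g: Tensor) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs "
                         f"ground truth {g.shape}")


def bce_loss(p, g) -> Tensor:
    """Mean binary cross-entropy −1/n Σ [g·log p + (1−g)·log(1−p)]."""
    p, g = _as_tensor(p), _as_tensor(g)
    _check_shapes(p, g)
    p = p.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    ll = g * p.log() + (1.0 - g) * (1.0 - p).log()
    return -ll.mean()


def dice_loss(p, g, epsilon: float = 1e-5) -> Tensor:
    """Soft Dice loss 1 − (2·Σpg + ε)/(Σp + Σg + ε).

    Predictions enter as probabilities (no thresholding), keeping the loss
    differentiable; ε rescues the empty-empty case (loss 0).
    """
    p, g = _as_tensor(p), _as_tensor(g)
    _check_shapes(p, g)
    intersection = (p * g).sum()
    denom = p.sum() + g.sum() + epsilon
    return 1.0 - (2.0 * intersection + epsilon) / denom


def total_loss(p, g, cfg: LossConfig | None = None) -> Tensor:
    """α·BCE + β·Dice, computed per subregion channel and averaged.

    ``p`` and ``g`` are (..., 3, H, W) or (3, H, W); the channel axis is the
    one of size 3 holding WT/TC/ET. For tensors without a channel axis of
    size 3 the loss is computed over the whole tensor.
    """
    cfg = cfg or LossConfig()
    p, g = _as_tensor(p), _as_tensor(g)
    _check_shapes(p, g)
    if p.ndim >= 3:
        channel_axis = p.ndim - 3
        n_channels = p.shape[channel_axis]
        terms = []
        for c in range(n_channels):
            index = [slice(None)] * p.ndim
            index[channel_axis] = c
            pc = _slice(p, tuple(index))
            gc = _slice(g, tuple(index))
            terms.append(cfg.alpha * bce_loss(pc, gc)
                         + cfg.beta * dice_loss(pc, gc, cfg.epsilon))
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out * (1.0 / n_channels)
    return cfg.alpha * bce_loss(p, g) + cfg.beta * dice_loss(p, g, cfg.epsilon)


def _slice(t: Tensor, index) -> Tensor:
    """Differentiable basic indexing."""
    out_data = t.data[index]

    def backward(grad):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[index] = grad
            t._accumulate(full)

    return Tensor._make(out_data, (t,), backward)
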