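"""Soft-Dice training loss, its analytic gradient, and the
deep-supervision weighted composite.

The soft Dice similarity between a probability patch p and a binary
ground-truth patch g is

    DSC(p, g) = (2 * sum(p * g) + eps) / (sum(p^2) + sum(g^2) + eps)

and the training loss is 1 - DSC.  The stabilizer eps (default 1.0)
appears in numerator and denominator so that an empty prediction on an
empty label patch — common, since half the sampled patches are not
vessel-centric — scores as perfect rather than 0/0.

The analytic gradient is kept as a verification oracle (training uses
automatic differentiation); with eps = 0 it reduces to

    dDSC/dp_j = 2 * [g_j * (sum p^2 + sum g^2) - 2 p_j * sum(p g)]
                  / (sum p^2 + sum g^2)^2 .
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "soft_dsc",
    "soft_dsc_loss",
    "soft_dsc_gradient",
    "ds_weights",
    "composite_loss",
    "soft_dsc_loss_tensor",
    "composite_loss_tensor",
]


def _check_pair(p, g):
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def soft_dsc(p, g, eps: float = 1.0) -> float:
    """Soft Dice similarity in [0, 1] between probabilities and labels."""
    p, g = _check_pair(p, g)
    num = 2.0 * (p * g).sum() + eps
    den = (p * p).sum() + (g * g).sum() + eps
    return float(num / den)


def soft_dsc_loss(p, g, eps: float = 1.0) -> float:
    """1 - soft_dsc, the per-patch training loss."""
    return 1.0 - soft_dsc(p, g, eps)


def soft_dsc_gradient(p, g, j, eps: float = 0.0) -> float:
    """Analytic d(DSC)/dp_j at the (possibly multi-) index ``j``."""
    p, g = _check_pair(p, g)
    den = (p * p).sum() + (g * g).sum() + eps
    inter = (p * g).sum()
    j = tuple(np.atleast_1d(j)) if np.ndim(j) else (int(j),)
    return float(2.0 * (g[j] * den - p[j] * (2.0 * inter + eps)) / den ** 2)


def ds_weights(n_heads: int) -> list[float]:
    """Per-head loss weights, final head last: 0.5 on the final output,
    the remaining 0.5 split equally across intermediate heads."""
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    if n_heads == 1:
        return [1.0]
    return [0.5 / (n_heads - 1)] * (n_heads - 1) + [0.5]


def composite_loss(head_outputs, g, w, eps: float = 1.0) -> float:
    """Weighted sum of per-head soft-Dice losses."""
    if len(head_outputs) != len(w):
        raise ValueError("one weight per head is required")
    return float(
        sum(wi * soft_dsc_loss(h, g, eps) for h, wi in zip(head_outputs, w))
    )


# ---------------------------------------------------------------------
# autodiff-graph versions used during training


def soft_dsc_loss_tensor(pred: Tensor, g: np.ndarray,
                         eps: float = 1.0) -> Tensor:
    """Mean per-sample soft-Dice loss over a (N, 1, X, Y, Z) batch."""
    g = np.asarray(g, dtype=pred.dtype)
    n = pred.shape[0]
    inter = ad.sum_except_batch(pred * g)
    psq = ad.sum_except_batch(pred.square())
    gsq = (g * g).sum(axis=tuple(range(1, g.ndim)))
    dice = (2.0 * inter + eps) / (psq + (gsq + eps))
    return (1.0 - dice).sum() / n


def composite_loss_tensor(heads, g: np.ndarray, w,
                          eps: float = 1.0) -> Tensor:
    """Deep-supervision composite loss on autodiff tensors."""
    if len(heads) != len(w):
        raise ValueError("one weight per head is required")
    total = None
    for h, wi in zip(heads, w):
        term = soft_dsc_loss_tensor(h, g, eps) * wi
        total = term if total is None else total + term
    return total
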