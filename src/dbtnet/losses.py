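"""Joint training objective: binary cross-entropy + weighted feature similarity.

For slice i with label y_i and predicted probability p_i,

    L_BCE(i) = -(y_i log p_i + (1 - y_i) log(1 - p_i))
    L_Sim(i) = mean_k (fhat_s[i,k] - fhat_d[i,k])^2
    L        = (1/N) * sum_i (L_BCE(i) + lambda * L_Sim(i))

The similarity term pulls the two branches' projected features together,
encouraging consistent (yet complementary, via the separate BCE path)
representations.  The reduction over the projection dimension is the mean by
default so that lambda's scale does not depend on d; ``sum`` is available.
Probabilities are clamped eps=1e-7 away from {0, 1} for numerical safety.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7


@dataclass(frozen=True)
class LossBreakdown:
    """Batch-mean BCE, similarity term, their weighted total, and batch size."""

    bce: float
    sim: float
    lam: float
    n: int

    @property
    def total(self) -> float:
        return self.bce + self.lam * self.sim


def bce_loss(y_true: np.ndarray, y_prob: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy; inputs broadcast, output >= 0."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_prob.size and (y_prob.min() < 0 or y_prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(y_prob, EPS, 1.0 - EPS)
    return -(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p))


def similarity_loss(fhat_s: np.ndarray, fhat_d: np.ndarray,
                    reduction: str = "mean") -> np.ndarray:
    """Per-sample squared difference between the two projections.

    For 2-D inputs ``(N, d)`` returns one value per sample; for 1-D inputs a
    scalar.  ``reduction`` over the projection dimension is ``mean`` (default)
    or ``sum``.
    """
    fhat_s = np.asarray(fhat_s, dtype=np.float64)
    fhat_d = np.asarray(fhat_d, dtype=np.float64)
    if fhat_s.shape != fhat_d.shape:
        raise ValueError("projected features must have identical shapes")
    sq = (fhat_s - fhat_d) ** 2
    if reduction == "mean":
        return sq.mean(axis=-1)
    if reduction == "sum":
        return sq.sum(axis=-1)
    raise ValueError("reduction must be 'mean' or 'sum'")


def total_loss(y_prob: np.ndarray, y_true: np.ndarray,
               fhat_s: np.ndarray, fhat_d: np.ndarray, lam: float = 0.3,
               reduction: str = "mean") -> LossBreakdown:
    """Batch joint loss: mean_i(BCE_i + lambda * Sim_i), with the breakdown."""
    y_prob = np.atleast_1d(np.asarray(y_prob, dtype=np.float64))
    y_true = np.atleast_1d(np.asarray(y_true, dtype=np.float64))
    if y_prob.size == 0:
        raise ValueError("empty batch")
    if y_prob.shape != y_true.shape:
        raise ValueError("predictions and labels must align")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    bce = float(bce_loss(y_true, y_prob).mean())
    sim = float(np.atleast_1d(similarity_loss(fhat_s, fhat_d, reduction)).mean())
    return LossBreakdown(bce=bce, sim=sim, lam=lam, n=int(y_prob.size))


def loss_gradients(y_prob: np.ndarray, y_true: np.ndarray,
                   fhat_s: np.ndarray, fhat_d: np.ndarray, lam: float,
                   reduction: str = "mean"):
    """Analytic gradients of the batch joint loss for the training loop.

    Returns ``(g_logit, g_fhat_s, g_fhat_d)`` where ``g_logit`` is the
    gradient with respect to the classifier logit (the BCE-through-sigmoid
    shortcut ``(p - y)/N``) and the ``g_fhat`` terms are the similarity
    gradients with respect to each projection.
    """
    n = y_prob.size
    g_logit = (np.clip(y_prob, EPS, 1 - EPS) - y_true) / n
    diff = fhat_s - fhat_d
    scale = 2.0 * lam / n
    if reduction == "mean":
        scale /= fhat_s.shape[-1]
    g_fhat_s = scale * diff
    return g_logit, g_fhat_s, -g_fhat_s
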