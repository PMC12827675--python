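"""Seeded CPU training loop for the dual-branch classifier.

Gradients of the joint objective (BCE through the sigmoid plus the weighted
feature-similarity term) are computed analytically in
:func:`dbtnet.losses.loss_gradients` and pushed through the network's
hand-derived backward pass.  Identical seeds and data give identical loss
trajectories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .backbones import build_backbone, get_spec
from .losses import LossBreakdown, loss_gradients, total_loss
from .model import DualNet, Prediction, _sigmoid
from .nn.optim import make_optimizer


class SingleBranchNet(nn.Module):
    """A single backbone + pooling + linear head baseline classifier."""

    def __init__(self, backbone: str = "tinycnn-shallow", pool_size: int = 1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = build_backbone(backbone, rng)
        self.pool = nn.AdaptiveAvgPool2d(pool_size)
        self.flat = nn.Flatten()
        dim = get_spec(backbone).feature_channels * pool_size ** 2
        self.head = nn.Linear(dim, 1, rng=rng)

    def forward(self, x):
        if x.ndim == 3:
            x = x[None]
        v = self.flat(self.pool(self.net(x)))
        logit = self.head(v)[:, 0]
        return None, Prediction(logit, _sigmoid(logit))

    def backward(self, g_logit, g_fhat_s=None, g_fhat_d=None):
        gv = self.head.backward(np.asarray(g_logit)[:, None])
        self.net.backward(self.pool.backward(self.flat.backward(gv)))


@dataclass
class Trainer:
    """Mini-batch trainer; works for :class:`DualNet` and the single-branch
    baseline (which has no similarity term)."""

    model: nn.Module
    lam: float = 0.3
    sim_reduction: str = "mean"
    optimizer_name: str = "adam"
    lr: float = 3e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        self._opt = make_optimizer(self.optimizer_name,
                                   self.model.parameters(), self.lr)
        self._rng = np.random.default_rng(self.seed)

    def train_step(self, x: np.ndarray, y: np.ndarray) -> LossBreakdown:
        self.model.train(True)
        self._opt.zero_grad()
        pair, pred = self.model.forward(x)
        if pair is None:
            fs = fd = np.zeros((y.size, 1))
            lam = 0.0
        else:
            fs, fd, lam = pair.fhat_s, pair.fhat_d, self.lam
        breakdown = total_loss(pred.prob, y, fs, fd, lam, self.sim_reduction)
        g_logit, g_fs, g_fd = loss_gradients(pred.prob, y, fs, fd, lam,
                                             self.sim_reduction)
        if pair is None:
            self.model.backward(g_logit)
        else:
            self.model.backward(g_logit, g_fs, g_fd)
        self._opt.step()
        return breakdown

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int,
            log_path: str | Path | None = None) -> list[LossBreakdown]:
        """Shuffled mini-batch training; returns one averaged breakdown per
        epoch and optionally appends them to a CSV log."""
        y = np.asarray(y, dtype=np.float64)
        history: list[LossBreakdown] = []
        for epoch in range(epochs):
            order = self._rng.permutation(len(y))
            bces, sims, ns = [], [], []
            for start in range(0, len(y), self.batch_size):
                idx = order[start:start + self.batch_size]
                b = self.train_step(x[idx], y[idx])
                bces.append(b.bce * b.n)
                sims.append(b.sim * b.n)
                ns.append(b.n)
            n = sum(ns)
            history.append(LossBreakdown(bce=sum(bces) / n, sim=sum(sims) / n,
                                         lam=self.lam, n=n))
        if log_path is not None:
            with open(log_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["epoch", "bce", "sim", "total"])
                for i, b in enumerate(history):
                    writer.writerow([i, f"{b.bce:.6f}", f"{b.sim:.6f}",
                                     f"{b.total:.6f}"])
        return history

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-slice probabilities in deterministic batches."""
        self.model.train(False)
        out = []
        for start in range(0, len(x), self.batch_size):
            _, pred = self.model.forward(x[start:start + self.batch_size])
            out.append(pred.prob)
        return np.concatenate(out)


def predict_probs(model: nn.Module, x: np.ndarray,
                  batch_size: int = 32) -> np.ndarray:
    model.train(False)
    out = []
    for start in range(0, len(x), batch_size):
        _, pred = model.forward(x[start:start + batch_size])
        out.append(pred.prob)
    return np.concatenate(out)
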