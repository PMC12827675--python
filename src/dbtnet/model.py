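"""The Dual-Net: two parallel CNN feature extractors fused for classification.

A shallow branch F_s and a deep branch F_d each process the same 3-channel
patch.  Their final feature maps are adaptively pooled and flattened into
vectors v_s and v_d, which are linearly projected into a shared d-dimensional
space (f_s_hat, f_d_hat) used by the feature-similarity loss.  The classifier
is a single fully connected layer with sigmoid activation.

Two fusion variants exist for what the classifier consumes:

* ``concat_raw`` (default): the concatenated original pooled features
  z = [v_d; v_s] of length d_d + d_s;
* ``concat_projected``: the concatenated projections
  z = [f_s_hat; f_d_hat] of length 2d.

Both are built; the variant is selected per prediction or fixed in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .backbones import DEEP, SHALLOW, build_backbone, get_spec

VARIANTS = ("concat_raw", "concat_projected")


@dataclass(frozen=True)
class DualNetConfig:
    """Backbone pair, shared projection dimension and fusion variant."""

    shallow: str = "tinycnn-shallow"
    deep: str = "tinycnn-deep"
    proj_dim: int = 256
    variant: str = "concat_raw"
    pool_size: int = 1            # adaptive-pool output side for both branches
    pretrained: str | None = None  # optional checkpoint path
    seed: int = 0

    def __post_init__(self):
        if get_spec(self.shallow).category != SHALLOW:
            raise ValueError(
                f"{self.shallow!r} is not a shallow backbone; shallow slot "
                f"requires one of the registry's shallow entries")
        if get_spec(self.deep).category != DEEP:
            raise ValueError(
                f"{self.deep!r} is not a deep backbone; deep slot requires "
                f"one of the registry's deep entries")
        if self.proj_dim <= 0:
            raise ValueError("projection dimension must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class FeaturePair:
    """Pooled branch features, their projections, and the classifier input."""

    v_s: np.ndarray       # (N, d_s)
    v_d: np.ndarray       # (N, d_d)
    fhat_s: np.ndarray    # (N, d)
    fhat_d: np.ndarray    # (N, d)
    z: np.ndarray         # (N, d_d + d_s) or (N, 2d) depending on variant


@dataclass
class Prediction:
    logit: np.ndarray     # (N,)
    prob: np.ndarray      # (N,), sigmoid of logit

    def __post_init__(self):
        assert np.allclose(self.prob, _sigmoid(self.logit))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 500))),
                    np.exp(np.clip(x, -500, None)) /
                    (1.0 + np.exp(np.clip(x, -500, None))))


class DualNet(nn.Module):
    """Dual-branch classifier; see the module docstring for the data flow."""

    def __init__(self, config: DualNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.shallow_net = build_backbone(config.shallow, rng)
        self.deep_net = build_backbone(config.deep, rng)
        self.pool_s = nn.AdaptiveAvgPool2d(config.pool_size)
        self.pool_d = nn.AdaptiveAvgPool2d(config.pool_size)
        self.flat_s = nn.Flatten()
        self.flat_d = nn.Flatten()
        area = config.pool_size ** 2
        self.d_s = get_spec(config.shallow).feature_channels * area
        self.d_d = get_spec(config.deep).feature_channels * area
        d = config.proj_dim
        self.proj_s = nn.Linear(self.d_s, d, rng=rng)
        self.proj_d = nn.Linear(self.d_d, d, rng=rng)
        self.head_raw = nn.Linear(self.d_d + self.d_s, 1, rng=rng)
        self.head_proj = nn.Linear(2 * d, 1, rng=rng)
        if config.pretrained:
            self.load_checkpoint(config.pretrained)

    # -- forward -------------------------------------------------------------
    def forward(self, x: np.ndarray,
                variant: str | None = None) -> tuple[FeaturePair, Prediction]:
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("input must be (N, 3, H, W)")
        variant = variant or self.config.variant
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        v_s = self.flat_s(self.pool_s(self.shallow_net(x)))
        v_d = self.flat_d(self.pool_d(self.deep_net(x)))
        fhat_s = self.proj_s(v_s)
        fhat_d = self.proj_d(v_d)
        if variant == "concat_raw":
            z = np.concatenate([v_d, v_s], axis=1)
            logit = self.head_raw(z)[:, 0]
        else:
            z = np.concatenate([fhat_s, fhat_d], axis=1)
            logit = self.head_proj(z)[:, 0]
        self._last_variant = variant
        pair = FeaturePair(v_s, v_d, fhat_s, fhat_d, z)
        return pair, Prediction(logit, _sigmoid(logit))

    # -- backward ------------------------------------------------------------
    def backward(self, g_logit: np.ndarray,
                 g_fhat_s: np.ndarray | None = None,
                 g_fhat_d: np.ndarray | None = None) -> None:
        """Backpropagate loss gradients.

        ``g_logit`` is dL/dlogit, shape (N,); ``g_fhat_*`` are the similarity
        term's gradients with respect to the projections, shape (N, d).  Both
        branches receive gradients from both paths.
        """
        g_logit = np.asarray(g_logit)[:, None]
        n = g_logit.shape[0]
        d = self.config.proj_dim
        if g_fhat_s is None:
            g_fhat_s = np.zeros((n, d))
        if g_fhat_d is None:
            g_fhat_d = np.zeros((n, d))
        if self._last_variant == "concat_raw":
            gz = self.head_raw.backward(g_logit)
            g_vd = gz[:, :self.d_d]
            g_vs = gz[:, self.d_d:]
        else:
            gz = self.head_proj.backward(g_logit)
            g_fhat_s = g_fhat_s + gz[:, :d]
            g_fhat_d = g_fhat_d + gz[:, d:]
            g_vd = np.zeros((n, self.d_d))
            g_vs = np.zeros((n, self.d_s))
        g_vs = g_vs + self.proj_s.backward(g_fhat_s)
        g_vd = g_vd + self.proj_d.backward(g_fhat_d)
        self.shallow_net.backward(self.pool_s.backward(self.flat_s.backward(g_vs)))
        self.deep_net.backward(self.pool_d.backward(self.flat_d.backward(g_vd)))

    # -- checkpointing -------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez_compressed(path, __config__=np.frombuffer(
            json.dumps(vars(self.config)).encode(), dtype=np.uint8), **arrays)

    def load_checkpoint(self, path: str | Path) -> None:
        with np.load(path) as data:
            n = len([k for k in data.files if k.startswith("arr_")])
            self.load_state_arrays([data[f"arr_{i}"] for i in range(n)])

    @staticmethod
    def from_checkpoint(path: str | Path) -> "DualNet":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
        cfg.pop("pretrained", None)
        model = DualNet(DualNetConfig(**cfg, pretrained=None))
        model.load_checkpoint(path)
        return model


def build_dual_net(config: DualNetConfig) -> DualNet:
    """Construct a Dual-Net with freshly (seeded) initialized heads,
    projections and pooling."""
    return DualNet(config)


def classify_variant(model: DualNet, x: np.ndarray, variant: str) -> Prediction:
    """Predict with a specific fusion variant (``concat_raw`` feeds the head
    the original pooled features; ``concat_projected`` feeds the projections)."""
    _, pred = model.forward(x, variant=variant)
    return pred
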