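"""Explainability: per-branch and fused Grad-CAM, and feature export.

Grad-CAM weights each channel of a branch's final convolutional feature map by
the spatial mean of the classification logit's gradient on that map, sums the
weighted channels, rectifies, upsamples to the input resolution and min-max
normalizes to [0, 1].

The fused map follows a direct-summation strategy: the two branches'
*un-normalized* weighted maps are upsampled to the common input grid first,
summed, then rectified and normalized once — preserving the branches'
relative magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .model import DualNet

BRANCHES = ("shallow", "deep")


@dataclass
class AttentionMap:
    heat: np.ndarray      # 2-D, values in [0, 1], input resolution
    branch: str           # "shallow" | "deep" | "fused"


def _normalize(cam: np.ndarray) -> np.ndarray:
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        return (cam - lo) / (hi - lo)
    # constant map: uniform attention (ones) if positive, no attention if zero
    return np.ones_like(cam) if hi > 0 else np.zeros_like(cam)


def _weighted_maps(model: DualNet, patch: np.ndarray) -> dict[str, np.ndarray]:
    """One forward/backward pass; returns each branch's raw gradient-weighted
    channel sum (2-D, pre-rectification, pre-normalization)."""
    x = patch[None] if patch.ndim == 3 else patch
    if x.shape[0] != 1:
        raise ValueError("Grad-CAM expects a single patch")
    model.eval()
    model.zero_grad()
    _, pred = model.forward(x)
    model.backward(np.ones_like(pred.logit))
    model.zero_grad()
    maps = {}
    for name, net in (("shallow", model.shallow_net), ("deep", model.deep_net)):
        tap = net.layers[-1]
        act, grad = tap.last_output, tap.last_grad
        if act is None or act.ndim != 4:
            raise ValueError(f"{name} branch has no convolutional feature map")
        weights = grad[0].mean(axis=(1, 2))            # (C,)
        maps[name] = np.tensordot(weights, act[0], axes=1)  # (h, w)
    return maps


def branch_cam(model: DualNet, patch: np.ndarray, branch: str) -> AttentionMap:
    """Grad-CAM attention map of one branch, at input resolution in [0, 1]."""
    if branch not in BRANCHES:
        raise ValueError(f"branch must be one of {BRANCHES}")
    raw = _weighted_maps(model, patch)[branch]
    out_shape = patch.shape[-2:]
    cam = np.maximum(raw, 0.0)
    cam = resize(cam, out_shape, order=1, preserve_range=True, mode="reflect")
    cam = np.maximum(cam, 0.0)
    return AttentionMap(_normalize(cam), branch)


def fused_cam(model: DualNet, patch: np.ndarray) -> AttentionMap:
    """Direct-summation fusion of the two branches' weighted maps."""
    raw = _weighted_maps(model, patch)
    out_shape = patch.shape[-2:]
    total = np.zeros(out_shape)
    for branch in BRANCHES:
        total += resize(raw[branch], out_shape, order=1, preserve_range=True,
                        mode="reflect")
    fused = np.maximum(total, 0.0)
    return AttentionMap(_normalize(fused), "fused")


def sum_attention(a: AttentionMap, b: AttentionMap) -> AttentionMap:
    """Elementwise sum of two (already upsampled) maps, renormalized."""
    if a.heat.shape != b.heat.shape:
        raise ValueError("attention maps must share a shape; upsample first")
    return AttentionMap(_normalize(np.maximum(a.heat + b.heat, 0.0)), "fused")


def overlay_png(heat: np.ndarray, image: np.ndarray, path: str | Path,
                alpha: float = 0.4) -> None:
    """Write a heatmap overlay PNG (presentation only)."""
    import imageio.v3 as iio
    base = np.stack([np.clip(image, 0, 1)] * 3, axis=-1)
    color = np.stack([heat, np.zeros_like(heat), 1.0 - heat], axis=-1)
    out = (1 - alpha) * base + alpha * color
    iio.imwrite(Path(path), (np.clip(out, 0, 1) * 255).astype(np.uint8))


def export_features(model: DualNet, patches: np.ndarray,
                    labels=None, path: str | Path | None = None) -> pd.DataFrame:
    """Extract fused and per-branch feature vectors for 2-D embedding tools.

    Returns one row per patch with columns ``z_*`` (classifier input),
    ``vs_*``/``vd_*`` (pooled branch features) and ``label``; optionally
    written to CSV at full precision.
    """
    model.eval()
    pair, _ = model.forward(patches)
    n = pair.z.shape[0]
    cols = {f"z_{i}": pair.z[:, i] for i in range(pair.z.shape[1])}
    cols.update({f"vs_{i}": pair.v_s[:, i] for i in range(pair.v_s.shape[1])})
    cols.update({f"vd_{i}": pair.v_d[:, i] for i in range(pair.v_d.shape[1])})
    cols["label"] = np.full(n, -1) if labels is None else np.asarray(labels)
    df = pd.DataFrame(cols)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.17g")
    return df
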