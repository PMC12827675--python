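"""Pseudo-color enhancement (PCE) of grayscale tomosynthesis patches.

A single-channel patch is mapped to a color image, converted to HSV, and the
three channels are adjusted independently:

* hue: a fixed integer shift ``delta_h``, wrapped modulo 180 into the 8-bit
  hue range [0, 179];
* saturation: scaled by ``alpha`` and clipped to [0, 255];
* value (brightness): scaled by ``beta`` and clipped to [0, 255].

The adjusted HSV image is converted back to RGB.  Default parameters are
``delta_h=30, alpha=0.8, beta=15``.  Note that ``beta=15`` drives every pixel
with value >= 17/255 of full scale to the 255 ceiling — the scaling is applied
literally, clipping included.

Because a channel-replicated grayscale image has zero saturation (and an
undefined hue), two colorization modes are provided for the grayscale-to-color
step that precedes the HSV adjustment:

* ``"replicate"``: the literal reading — gray is copied to R=G=B, so the hue
  shift acts on a degenerate hue channel;
* ``"intensity_to_hue"`` (default): intensity is mapped directly into the hue
  channel (H = round(I*179), S = 255, V = round(I*255)), which produces a
  genuinely colored intermediate.

Hue uses the 8-bit convention H in [0, 179] (half-degrees), matching the
mod-180 wrap; conversions between RGB and HSV delegate to scikit-image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

COLORIZE_MODES = ("replicate", "intensity_to_hue")


@dataclass(frozen=True)
class PceParams:
    """Enhancement parameters: hue shift, saturation scale, value scale."""

    delta_h: int = 30
    alpha: float = 0.8
    beta: float = 15.0
    colorize_mode: str = "intensity_to_hue"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.colorize_mode not in COLORIZE_MODES:
            raise ValueError(f"colorize_mode must be one of {COLORIZE_MODES}")
        if float(self.delta_h) != int(self.delta_h):
            raise ValueError("delta_h must be an integer hue shift")


def _as_int_channel(x: np.ndarray, name: str, hi: int) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.floor(arr + 0.5)  # round-half-up policy for float input
    arr = arr.astype(np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > hi):
        raise ValueError(f"{name} channel values must lie in [0, {hi}]")
    return arr


def adjust_hue(h: np.ndarray, delta_h: int) -> np.ndarray:
    """Shift the 8-bit hue channel by ``delta_h``, wrapping modulo 180."""
    if float(delta_h) != int(delta_h):
        raise ValueError("delta_h must be an integer")
    h = _as_int_channel(h, "hue", 179)
    return (h + int(delta_h)) % 180


def adjust_saturation(s: np.ndarray, alpha: float) -> np.ndarray:
    """Scale the saturation channel by ``alpha``, clipping at 255."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    s = np.asarray(s, dtype=np.float64)
    if s.size and (s.min() < 0 or s.max() > 255):
        raise ValueError("saturation values must lie in [0, 255]")
    return np.minimum(s * alpha, 255.0)


def adjust_value(v: np.ndarray, beta: float) -> np.ndarray:
    """Scale the value (brightness) channel by ``beta``, clipping at 255."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    v = np.asarray(v, dtype=np.float64)
    if v.size and (v.min() < 0 or v.max() > 255):
        raise ValueError("value-channel values must lie in [0, 255]")
    return np.minimum(v * beta, 255.0)


def _to_uint8(patch: np.ndarray) -> np.ndarray:
    """Float [0,1] view -> 8-bit integer view, round half up."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.min() < 0 or patch.max() > 1:
        raise ValueError("grayscale patch must be normalized to [0, 1]")
    return np.floor(patch * 255.0 + 0.5).astype(np.uint8)


def _colorize_hsv8(gray8: np.ndarray, mode: str):
    """Grayscale 8-bit image -> (H, S, V) integer channels, 8-bit convention."""
    if mode == "replicate":
        rgb = np.stack([gray8] * 3, axis=-1).astype(np.float64) / 255.0
        hsv = rgb2hsv(rgb)
        h8 = np.floor(hsv[..., 0] * 180.0 + 0.5).astype(np.int64) % 180
        s8 = np.floor(hsv[..., 1] * 255.0 + 0.5).astype(np.int64)
        v8 = np.floor(hsv[..., 2] * 255.0 + 0.5).astype(np.int64)
        return h8, s8, v8
    # intensity_to_hue: intensity drives hue, full saturation
    intensity = gray8.astype(np.float64) / 255.0
    h8 = np.floor(intensity * 179.0 + 0.5).astype(np.int64)
    s8 = np.full(gray8.shape, 255, dtype=np.int64)
    v8 = gray8.astype(np.int64)
    return h8, s8, v8


def hsv8_to_rgb(h8: np.ndarray, s8: np.ndarray, v8: np.ndarray) -> np.ndarray:
    """8-bit-convention HSV channels -> float RGB image in [0, 1]."""
    hsv = np.stack([np.asarray(h8, dtype=np.float64) / 180.0,
                    np.asarray(s8, dtype=np.float64) / 255.0,
                    np.asarray(v8, dtype=np.float64) / 255.0], axis=-1)
    return np.clip(hsv2rgb(hsv), 0.0, 1.0)


def enhance_patch(patch: np.ndarray, params: PceParams | None = None) -> np.ndarray:
    """Enhance a grayscale patch (2-D float array in [0, 1]) to pseudo-color.

    Returns an ``(H, W, 3)`` float RGB image in [0, 1] (8-bit quantized).
    The channel operations run in the order hue -> saturation -> value.
    """
    params = params or PceParams()
    gray8 = _to_uint8(patch)
    h8, s8, v8 = _colorize_hsv8(gray8, params.colorize_mode)
    h8 = adjust_hue(h8, params.delta_h)
    s8 = adjust_saturation(s8, params.alpha)
    v8 = adjust_value(v8, params.beta)
    # merge back at 8-bit precision before the RGB conversion
    s8 = np.floor(s8 + 0.5)
    v8 = np.floor(v8 + 0.5)
    return hsv8_to_rgb(h8, s8, v8)


def histogram_equalize(patch: np.ndarray) -> np.ndarray:
    """Standard 8-bit histogram equalization; returns a float patch in [0, 1].

    The classic lookup ``round(255 * (cdf - cdf_min) / (n_pixels - cdf_min))``
    is used.  A constant image (degenerate histogram) is returned unchanged.
    """
    gray8 = _to_uint8(patch)
    hist = np.bincount(gray8.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = gray8.size - cdf_min
    if denom == 0:
        warnings.warn("constant image: histogram equalization is the identity")
        return np.asarray(patch, dtype=np.float64)
    lut = np.floor(255.0 * (cdf - cdf_min) / denom + 0.5).astype(np.uint8)
    return lut[gray8].astype(np.float64) / 255.0


def write_png(image: np.ndarray, path) -> None:
    """Write a grayscale or RGB float image in [0, 1] as an 8-bit PNG."""
    import imageio.v3 as iio
    arr = np.floor(np.clip(np.asarray(image, dtype=np.float64), 0, 1)
                   * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(path, arr)


def read_png(path) -> np.ndarray:
    """Read an 8-bit PNG back to a float image in [0, 1]."""
    import imageio.v3 as iio
    return np.asarray(iio.imread(path), dtype=np.float64) / 255.0


def enhance_for_model(patch: np.ndarray, mode: str = "pce",
                      params: PceParams | None = None) -> np.ndarray:
    """Produce the 3-channel model input ``(3, H, W)`` for a grayscale patch.

    ``mode`` is one of ``off`` (channel replication only), ``pce`` or
    ``histeq``.
    """
    if mode == "pce":
        rgb = enhance_patch(patch, params)
        return np.moveaxis(rgb, -1, 0)
    if mode == "histeq":
        eq = histogram_equalize(patch)
        return np.stack([eq] * 3, axis=0)
    if mode == "off":
        p = np.asarray(patch, dtype=np.float64)
        return np.stack([p] * 3, axis=0)
    raise ValueError("mode must be one of {'off', 'pce', 'histeq'}")
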