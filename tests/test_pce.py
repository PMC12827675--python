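"""Pseudo-color enhancement: exact channel arithmetic and colorspace contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbtnet import pce


class TestChannelOps:
    def test_hue_shift_closed_form_exhaustive(self):
        """(H + dH) mod 180 over the full 8-bit hue grid and a shift grid."""
        h = np.arange(180)
        for dh in (-200, -30, 0, 1, 30, 179, 180, 359):
            np.testing.assert_array_equal(pce.adjust_hue(h, dh), (h + dh) % 180)

    @pytest.mark.parametrize("h,dh,expected", [(160, 30, 10), (77, 0, 77),
                                               (179, 1, 0)])
    def test_hue_shift_examples(self, h, dh, expected):
        assert pce.adjust_hue(np.array([h]), dh)[0] == expected

    def test_saturation_value_closed_form_exhaustive(self):
        """min(x*scale, 255) over the full 8-bit grid for several scales."""
        x = np.arange(256)
        for scale in (0.0, 0.5, 0.8, 1.0, 2.0, 15.0):
            np.testing.assert_allclose(pce.adjust_saturation(x, scale),
                                       np.minimum(x * scale, 255))
            np.testing.assert_allclose(pce.adjust_value(x, scale),
                                       np.minimum(x * scale, 255))

    def test_ceilings_attained(self):
        assert pce.adjust_hue(np.array([179]), 0)[0] == 179
        assert pce.adjust_saturation(np.array([200]), 2.0)[0] == 255
        assert pce.adjust_value(np.array([20]), 15.0)[0] == 255
        assert pce.adjust_value(np.array([17]), 15.0)[0] == 255  # 17*15=255

    @pytest.mark.parametrize("fn", [pce.adjust_saturation, pce.adjust_value])
    def test_negative_scale_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.array([10.0]), -0.5)

    def test_out_of_range_channels_rejected(self):
        with pytest.raises(ValueError):
            pce.adjust_hue(np.array([185]), 0)
        with pytest.raises(ValueError):
            pce.adjust_saturation(np.array([300.0]), 1.0)

    @given(st.integers(min_value=-1000, max_value=1000))
    @settings(deadline=None, max_examples=50)
    def test_hue_periodicity(self, dh):
        h = np.arange(180)
        np.testing.assert_array_equal(pce.adjust_hue(h, dh),
                                      pce.adjust_hue(h, dh + 180))

    @given(st.floats(min_value=0, max_value=20))
    @settings(deadline=None, max_examples=50)
    def test_scaling_monotone_in_input(self, scale):
        x = np.arange(256, dtype=float)
        for fn in (pce.adjust_saturation, pce.adjust_value):
            out = fn(x, scale)
            assert np.all(np.diff(out) >= 0)


class TestEnhancePatch:
    @pytest.fixture
    def patch(self):
        rng = np.random.default_rng(0)
        return rng.random((32, 32))

    def test_identity_parameters_round_trip(self, patch):
        """dH=0, alpha=1, beta=1 in replicate mode is the identity up to 8-bit
        quantization (at most one intensity level per pixel)."""
        params = pce.PceParams(0, 1.0, 1.0, "replicate")
        rgb = pce.enhance_patch(patch, params)
        gray8 = np.floor(patch * 255 + 0.5)
        for ch in range(3):
            assert np.max(np.abs(rgb[..., ch] * 255 - gray8)) <= 1.0

    @pytest.mark.parametrize("mode", ["replicate", "intensity_to_hue"])
    def test_output_shape_and_range(self, patch, mode):
        rgb = pce.enhance_patch(patch, pce.PceParams(colorize_mode=mode))
        assert rgb.shape == patch.shape + (3,)
        assert rgb.min() >= 0 and rgb.max() <= 1

    def test_default_parameters(self):
        params = pce.PceParams()
        assert (params.delta_h, params.alpha, params.beta) == (30, 0.8, 15.0)

    def test_beta_saturates_bright_constant_patch(self):
        """A constant patch at >= 17/255 of full scale hits the value ceiling,
        so the enhanced image has max-brightness pixels everywhere."""
        patch = np.full((8, 8), 20 / 255)
        rgb = pce.enhance_patch(patch, pce.PceParams(0, 1.0, 15.0,
                                                     "intensity_to_hue"))
        hsv_v = rgb.max(axis=-1)  # V channel of HSV is the max of RGB
        np.testing.assert_allclose(hsv_v, 1.0, atol=1 / 255)

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            pce.enhance_patch(np.empty((0, 0)))

    def test_deterministic(self, patch):
        a = pce.enhance_patch(patch, pce.PceParams())
        b = pce.enhance_patch(patch.copy(), pce.PceParams())
        np.testing.assert_array_equal(a, b)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_range_closure_random_patches(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.random((8, 8))
        params = pce.PceParams(int(rng.integers(-180, 360)),
                               float(rng.uniform(0, 3)),
                               float(rng.uniform(0, 20)),
                               ["replicate", "intensity_to_hue"][seed % 2])
        gray8 = np.floor(patch * 255 + 0.5).astype(np.uint8)
        h8, s8, v8 = pce._colorize_hsv8(gray8, params.colorize_mode)
        h8 = pce.adjust_hue(h8, params.delta_h)
        s8 = pce.adjust_saturation(s8, params.alpha)
        v8 = pce.adjust_value(v8, params.beta)
        assert h8.min() >= 0 and h8.max() <= 179
        assert s8.min() >= 0 and s8.max() <= 255
        assert v8.min() >= 0 and v8.max() <= 255


class TestHistogramEqualization:
    def test_two_level_extremes_preserved(self):
        patch = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = pce.histogram_equalize(patch)
        np.testing.assert_array_equal(np.unique(out), [0.0, 1.0])

    def test_constant_image_unchanged(self):
        patch = np.full((4, 4), 0.5)
        with pytest.warns(UserWarning):
            out = pce.histogram_equalize(patch)
        np.testing.assert_array_equal(out, patch)

    def test_linear_ramp_approximately_identity(self):
        """A uniform-histogram ramp maps approximately to itself; verified
        against a direct CDF-mapping oracle."""
        gray8 = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        patch = gray8 / 255.0
        out8 = np.floor(pce.histogram_equalize(patch) * 255 + 0.5)

        # oracle: y = round(255*(cdf(x)-cdf_min)/(n-cdf_min))
        hist = np.bincount(gray8.ravel(), minlength=256)
        cdf = np.cumsum(hist)
        oracle = np.floor(255 * (cdf[gray8] - cdf.min()) /
                          (gray8.size - cdf.min()) + 0.5)
        np.testing.assert_array_equal(out8, oracle)
        assert np.max(np.abs(out8 - gray8)) <= 2  # near-identity

    def test_output_spans_full_range(self):
        rng = np.random.default_rng(1)
        out = pce.histogram_equalize(rng.random((64, 64)))
        assert out.min() == 0.0 and out.max() == 1.0


def test_png_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    gray = rng.random((16, 16))
    path = tmp_path / "patch.png"
    pce.write_png(gray, path)
    back = pce.read_png(path)
    assert np.max(np.abs(back - gray)) <= 1 / 255  # 8-bit quantization only
    rgb = pce.enhance_patch(gray, pce.PceParams())
    pce.write_png(rgb, tmp_path / "rgb.png")
    back_rgb = pce.read_png(tmp_path / "rgb.png")
    assert back_rgb.shape == rgb.shape


def test_enhance_for_model_modes():
    patch = np.random.default_rng(2).random((16, 16))
    for mode in ("off", "pce", "histeq"):
        x = pce.enhance_for_model(patch, mode)
        assert x.shape == (3, 16, 16)
        assert x.min() >= 0 and x.max() <= 1
    with pytest.raises(ValueError):
        pce.enhance_for_model(patch, "bogus")
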