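"""Unit and property tests for the shared image operators."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from secrflux import ops
from secrflux.errors import (
    DegenerateHistogramError,
    InputError,
    ParameterError,
)
from secrflux.stack import ImageStack


# ---------------------------------------------------------------------------
# rolling-ball background subtraction


class TestRollingBall:
    def test_flat_image_removed_entirely(self):
        out = ops.rolling_ball_background_subtract(np.full((64, 64), 100.0), 10)
        assert np.abs(out).max() <= 1.0

    def test_spike_retained_background_removed(self):
        """Oracle: grayscale opening with a ball structuring element gives
        the same background for an isolated spike on a flat field."""
        img = np.full((64, 64), 50.0)
        img[30, 30] = 500.0
        out = ops.rolling_ball_background_subtract(img, 10)
        r = 10
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        d2 = yy**2 + xx**2
        ball = np.where(d2 <= r * r, np.sqrt(np.clip(r * r - d2, 0, None)), -np.inf)
        bg_oracle = ndi.grey_dilation(ndi.grey_erosion(img, structure=ball), structure=ball)
        oracle = img - bg_oracle
        assert out[30, 30] == pytest.approx(oracle[30, 30], abs=1e-9)
        assert abs(out[30, 30] - 450.0) <= 0.05 * 450.0
        rest = out.copy()
        rest[30, 30] = 0.0
        assert np.abs(rest).max() <= 1.0

    def test_output_never_negative_and_bounded_by_input(self, rng):
        img = rng.poisson(40, (48, 48)).astype(float)
        out = ops.rolling_ball_background_subtract(img, 8)
        assert (out >= 0).all()
        assert (out <= img + 1e-9).all()

    def test_idempotent_within_tolerance(self):
        img = np.full((48, 48), 100.0)
        for y, x, v in [(10, 10, 300.0), (30, 35, 450.0), (40, 12, 250.0)]:
            img[y, x] = v
        once = ops.rolling_ball_background_subtract(img, 8)
        twice = ops.rolling_ball_background_subtract(once, 8)
        # background of an already-subtracted image is nearly zero
        assert np.abs(twice - once).max() <= 0.05 * max(once.max(), 1.0)

    def test_radius_validation(self):
        with pytest.raises(ParameterError):
            ops.rolling_ball_background_subtract(np.zeros((10, 10)), 0.5)
        with pytest.raises(ParameterError):
            ops.rolling_ball_background_subtract(np.zeros((10, 10)), 11)


# ---------------------------------------------------------------------------
# Otsu thresholding


def brute_force_otsu(img: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer over all 8-bit splits."""
    vals = np.arange(256, dtype=float)
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(255):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (vals[: t + 1] * p[: t + 1]).sum() / w0
        m1 = (vals[t + 1 :] * p[t + 1 :]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        img = np.full((30, 30), 10.0)
        img.ravel()[:100] = 200.0
        thr, mask = ops.otsu_threshold(img)
        assert 10 < thr < 200
        assert mask.sum() == 100

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        arrays(
            np.uint8,
            (32, 32),
            elements=st.integers(min_value=0, max_value=255),
        )
    )
    def test_matches_brute_force_on_random_8bit_images(self, img):
        if img.min() == img.max():
            return
        thr, _ = ops.otsu_threshold(img)
        assert int(round(thr)) == brute_force_otsu(img)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            ops.otsu_threshold(np.full((16, 16), 7.0))


class TestLocalOtsu:
    def test_matches_global_on_interior_of_bimodal_image(self):
        img = np.full((64, 64), 20.0)
        img[20:40, 20:40] = 200.0
        gmask = img > ops.otsu_threshold(img)[0]
        lmask = ops.local_otsu_threshold(img, 31)
        interior = np.zeros((64, 64), bool)
        interior[8:56, 8:56] = True
        assert (gmask[interior] == lmask[interior]).all()

    def test_detects_dim_spot_global_otsu_misses(self):
        img = np.full((64, 64), 10.0)
        img[10:18, 10:18] = 200.0  # bright spot dominates the histogram
        img[45:51, 45:51] = 22.0  # locally distinct, globally below threshold
        gmask = img > ops.otsu_threshold(img)[0]
        lmask = ops.local_otsu_threshold(img, 21)
        assert not gmask[45:51, 45:51].any()
        assert lmask[47, 47]
        assert lmask[13, 13]

    def test_blank_image_all_background(self):
        assert not ops.local_otsu_threshold(np.zeros((32, 32)), 11).any()

    def test_window_validation(self):
        with pytest.raises(ParameterError):
            ops.local_otsu_threshold(np.zeros((32, 32)), 10)  # even
        with pytest.raises(ParameterError):
            ops.local_otsu_threshold(np.zeros((8, 8)), 11)  # larger than image


# ---------------------------------------------------------------------------
# binary erosion


class TestErodeBinary:
    def test_square_shrinks_by_one_per_iteration(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        eroded = ops.erode_binary(mask, 2)
        expected = np.zeros((14, 14), bool)
        expected[4:10, 4:10] = True
        assert (eroded == expected).all()

    def test_identity_and_empty(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        assert (ops.erode_binary(mask, 0) == mask).all()
        assert not ops.erode_binary(np.zeros((8, 8), bool), 3).any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(np.bool_, (20, 20), elements=st.booleans()),
        st.integers(min_value=0, max_value=3),
    )
    def test_monotone_shrinking(self, mask, iterations):
        out = ops.erode_binary(mask, iterations)
        assert not (out & ~mask).any()
        assert out.sum() <= mask.sum()


# ---------------------------------------------------------------------------
# bleach correction


class TestBleachCorrect:
    @pytest.mark.parametrize("k", [0.001, 0.005, 0.01, 0.02])
    def test_recovers_planted_rate_noise_free(self, k):
        t = np.arange(200)
        base = np.full((8, 8), 80.0)
        frames = base[None] * np.exp(-k * t)[:, None, None]
        stack = ImageStack(frames[:, None])
        corrected, fit = ops.bleach_correct(stack)
        assert abs(fit.rate_per_frame - k) <= 0.02 * k
        means = corrected.data[:, 0].mean(axis=(1, 2))
        assert np.abs(means - means[0]).max() <= 0.01 * means[0]

    def test_constant_stack_is_identity(self):
        stack = ImageStack(np.full((20, 1, 8, 8), 50.0))
        corrected, fit = ops.bleach_correct(stack)
        assert fit.rate_per_frame <= 1e-4
        assert np.abs(corrected.data - stack.data).max() <= 0.001 * 50.0

    def test_two_frames_rejected(self):
        with pytest.raises(InputError):
            ops.bleach_correct(ImageStack(np.ones((2, 1, 4, 4))))


# ---------------------------------------------------------------------------
# bandpass filter


class TestBandpass:
    @pytest.mark.parametrize("method", ["dog", "fft"])
    def test_constant_image_maps_to_zero(self, method):
        out = ops.bandpass_filter(np.full((64, 64), 7.0), 3, 20, method=method)
        assert np.abs(out).max() <= 1e-6

    @pytest.mark.parametrize("method", ["dog", "fft"])
    def test_grating_transfer(self, method):
        # periods divide the image width so the gratings are FFT-periodic
        x = np.arange(400)
        inside = np.tile(np.sin(2 * np.pi * x / 10), (400, 1))
        too_large = np.tile(np.sin(2 * np.pi * x / 200), (400, 1))
        keep = ops.bandpass_filter(inside, 3, 20, method=method)
        kill = ops.bandpass_filter(too_large, 3, 20, method=method)
        assert keep.std() / inside.std() >= 0.5
        assert kill.std() / too_large.std() <= 0.1

    def test_linearity(self, rng):
        img = rng.normal(0, 1, (64, 64))
        out1 = ops.bandpass_filter(2.5 * img, 3, 20)
        out2 = 2.5 * ops.bandpass_filter(img, 3, 20)
        assert np.allclose(out1, out2, atol=1e-10)

    def test_parameter_order_enforced(self):
        with pytest.raises(ParameterError):
            ops.bandpass_filter(np.zeros((16, 16)), 20, 3)
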