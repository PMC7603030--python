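"""Shared image operators: background subtraction, thresholding, morphology,
photobleaching correction and bandpass filtering.

These are the primitives every analysis stage builds on. Each wraps an
established implementation (scikit-image / scipy.ndimage) behind the
package's error contracts and defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.optimize
from skimage import filters, restoration, transform
from skimage.filters import rank
from skimage.morphology import footprint_rectangle
from skimage.util import img_as_ubyte

from .errors import (
    DegenerateHistogramError,
    FitError,
    InputError,
    ParameterError,
)
from .stack import ImageStack

#: 3x3 cross (4-connectivity) structuring element used for binary erosion.
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def rolling_ball_background_subtract(
    image: np.ndarray,
    radius_px: float = 50,
    downscale: int | None = None,
) -> np.ndarray:
    """Subtract a smooth background estimated by the rolling-ball method.

    The background is the surface traced by a ball of the given radius
    rolled under the intensity landscape; it is everywhere <= the image,
    so the result is non-negative up to clipping of interpolation noise.

    Parameters
    ----------
    image
        2-D intensity array.
    radius_px
        Ball radius in pixels; structures wider than ~2*radius are treated
        as background.
    downscale
        Optional integer factor: estimate the background on a downscaled
        copy (radius scaled accordingly) and upsample it. Large radii are
        dominated by smooth structure, so this trades negligible accuracy
        for a large speed-up. Default: 1 for radius <= 16, else radius//12.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("rolling-ball expects a 2-D image")
    if radius_px < 1:
        raise ParameterError("rolling-ball radius must be >= 1 pixel")
    if radius_px > min(image.shape):
        raise ParameterError(
            f"rolling-ball radius {radius_px} exceeds the smallest image "
            f"dimension {min(image.shape)}"
        )
    if downscale is None:
        downscale = 1 if radius_px <= 16 else max(1, int(radius_px) // 12)
    if downscale > 1:
        small = transform.rescale(
            image, 1.0 / downscale, anti_aliasing=True, preserve_range=True
        )
        bg_small = restoration.rolling_ball(small, radius=radius_px / downscale)
        background = transform.resize(
            bg_small, image.shape, preserve_range=True
        )
        # resizing can overshoot the image surface; keep the bound bg <= image
        background = np.minimum(background, image)
    else:
        background = restoration.rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0, None)


def otsu_threshold(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Global Otsu threshold: maximize between-class intensity variance.

    Returns the threshold and the foreground mask ``image > threshold``.
    Raises :class:`DegenerateHistogramError` on a constant image — callers
    decide whether that means "nothing detected" or a hard failure.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ParameterError("empty image")
    finite = image[np.isfinite(image)]
    if finite.size == 0 or finite.min() == finite.max():
        raise DegenerateHistogramError(
            "image has fewer than 2 distinct intensity values"
        )
    thr = float(filters.threshold_otsu(image))
    return thr, image > thr


def local_otsu_threshold(image: np.ndarray, window_px: int = 51) -> np.ndarray:
    """Per-pixel Otsu threshold computed in a sliding square window.

    The image is rescaled to 8-bit for the rank filter; pixels whose local
    window is flat (degenerate histogram) end up below-or-equal to their
    local threshold and are reported as background.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("local Otsu expects a 2-D image")
    if window_px < 3 or window_px % 2 == 0:
        raise ParameterError("window_px must be odd and >= 3")
    if window_px > min(image.shape):
        raise ParameterError("window larger than the image")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=bool)
    scaled = img_as_ubyte((image - lo) / (hi - lo))
    footprint = footprint_rectangle((window_px, window_px))
    local_thr = rank.otsu(scaled, footprint)
    return scaled > local_thr


def erode_binary(
    mask: np.ndarray, iterations: int, structure: np.ndarray = CROSS
) -> np.ndarray:
    """Erode a binary mask; iterations=0 is the identity.

    Default structuring element is the 3x3 cross (4-connectivity).
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    return ndi.binary_erosion(mask, structure=structure, iterations=iterations)


@dataclass
class BleachFit:
    """Mono-exponential photobleaching model m(t) = A*exp(-k*t) + c fitted
    to per-frame mean intensities (t in frames)."""

    amplitude: float
    rate_per_frame: float
    offset: float
    residual_rms: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate_per_frame * np.asarray(t)) + self.offset


def fit_bleach(frame_means: np.ndarray) -> BleachFit:
    """Fit A*exp(-k*t)+c to a frame-mean intensity series by least squares.

    Initialization is log-linear: the offset is guessed just below the
    series minimum and the rate from the slope of log(m - offset).
    """
    m = np.asarray(frame_means, dtype=float)
    if m.size < 3:
        raise InputError("bleach fit needs at least 3 frames")
    t = np.arange(m.size, dtype=float)
    c0 = max(0.0, m.min() - 0.05 * (m.max() - m.min()) - 1e-12)
    resid = np.clip(m - c0, 1e-12, None)
    slope, intercept = np.polyfit(t, np.log(resid), 1)
    k0 = max(-slope, 1e-6)
    a0 = max(float(np.exp(intercept)), 1e-12)

    def model(t, a, k, c):
        return a * np.exp(-k * t) + c

    try:
        popt, _ = scipy.optimize.curve_fit(
            model,
            t,
            m,
            p0=(a0, k0, c0),
            bounds=([0, 0, 0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            "exponential bleach fit did not converge",
            diagnostics={"p0": (a0, k0, c0), "frame_means": m.tolist()},
        ) from exc
    a, k, c = (float(v) for v in popt)
    if not all(np.isfinite((a, k, c))):
        raise FitError("bleach fit returned non-finite parameters")
    rms = float(np.sqrt(np.mean((model(t, a, k, c) - m) ** 2)))
    return BleachFit(amplitude=a, rate_per_frame=k, offset=c, residual_rms=rms)


def bleach_correct(stack: ImageStack, channel: int = 0) -> tuple[ImageStack, BleachFit]:
    """Correct a movie for photobleaching by an exponential fit on frame means.

    Each frame t is rescaled by m_hat(0)/m_hat(t) where m_hat is the fitted
    decay, so that the corrected frame-mean series is flat within the fit
    residuals. Detection downstream then behaves uniformly across the movie.
    """
    frames = stack.data[:, channel].astype(float)
    fit = fit_bleach(frames.mean(axis=(1, 2)))
    t = np.arange(stack.n_frames, dtype=float)
    predicted = fit.predict(t)
    if np.any(predicted <= 0):
        raise FitError("fitted bleach curve is non-positive")
    factors = predicted[0] / predicted
    corrected_data = stack.data.astype(float).copy()
    corrected_data[:, channel] = frames * factors[:, None, None]
    corrected = ImageStack(
        data=corrected_data,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        timepoints_min=stack.timepoints_min,
        channel_names=stack.channel_names,
    )
    return corrected, fit


def bandpass_filter(
    image: np.ndarray,
    small_px: float = 3,
    large_px: float = 40,
    method: str = "dog",
) -> np.ndarray:
    """Bandpass filter suppressing structures smaller than ``small_px`` and
    larger than ``large_px``.

    method="dog" (default) uses a difference of Gaussians with sigmas
    small_px/2 and large_px/2; method="fft" applies a radial annulus in the
    frequency domain passing spatial periods in [small_px, large_px] with a
    smooth (Gaussian-edged) rolloff. Both are linear in the input.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("bandpass expects a 2-D image")
    if not (0 < small_px < large_px):
        raise ParameterError("need 0 < small_px < large_px")
    if method == "dog":
        return filters.difference_of_gaussians(
            image, low_sigma=small_px / 2.0, high_sigma=large_px / 2.0
        )
    if method == "fft":
        fy = np.fft.fftfreq(image.shape[0])[:, None]
        fx = np.fft.fftfreq(image.shape[1])[None, :]
        r = np.hypot(fy, fx)  # cycles / pixel
        f_lo, f_hi = 1.0 / large_px, 1.0 / small_px
        # Gaussian-edged annulus: high-pass kills periods >> large_px,
        # low-pass rolls off beyond the small_px cutoff frequency
        hp = 1.0 - np.exp(-0.5 * (r / (f_lo / 2)) ** 2)
        lp = np.exp(-0.5 * (np.clip(r - f_hi, 0, None) / (0.25 * f_hi)) ** 2)
        return np.real(np.fft.ifft2(np.fft.fft2(image) * hp * lp))
    raise ParameterError(f"unknown bandpass method {method!r}")
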