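"""De-noising of masked signal channels before spot detection.

The fixed pipeline order is: mask → wavelet background/noise subtraction →
Gaussian smoothing → percentile intensity cut.  Each step is exposed
separately; :func:`preprocess_channel` chains them.

The wavelet step (WBNS) decomposes the image with a multi-level B3-spline
à-trous (stationary) wavelet transform.  The coarsest approximation is the
smooth background; the finest detail level(s) carry pixel-scale noise.  Both
estimates are subtracted and the result clamped at zero, leaving compact
fluorescent features on a near-zero floor.

The percentile cut removes the dimmest fraction of the remaining positive
pixels.  Zeros produced by masking are excluded from the percentile so the
threshold does not depend on how much of the frame the ROI covers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projection import Projection2D

#: 1-D B3-spline kernel of the à-trous transform.
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class PreprocessParams:
    """De-noising parameters.

    sigma
        Gaussian smoothing width in pixels (standard deviation); 0 disables.
    percentile
        Percentage of positive intensities cut off, in [0, 100).
    wavelet_resolution_px
        Characteristic feature size for background estimation (pixels ≥ 1);
        sets the à-trous decomposition depth ceil(log2(res)) + 1.
    noise_levels
        Number of finest detail levels treated as noise (≥ 1).
    """

    sigma: float = 1.0
    percentile: float = 90.0
    wavelet_resolution_px: float = 3.0
    noise_levels: int = 1

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.percentile < 100:
            raise ValueError("percentile must be in [0, 100)")
        if self.wavelet_resolution_px < 1:
            raise ValueError("wavelet_resolution_px must be >= 1")
        if self.noise_levels < 1:
            raise ValueError("noise_levels must be >= 1")


def _as_plane(image) -> np.ndarray:
    plane = image.plane if isinstance(image, Projection2D) else np.asarray(image)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {plane.ndim}-D")
    return np.asarray(plane, dtype=np.float64)


def _wrap(image, plane: np.ndarray):
    if isinstance(image, Projection2D):
        return image.with_plane(plane)
    return plane


def _atrous_smooth(img: np.ndarray, level: int) -> np.ndarray:
    """Separable B3-spline smoothing with 2**level - 1 zeros between taps."""
    spacing = 2 ** level
    kernel = np.zeros(4 * spacing + 1)
    kernel[::spacing] = _B3
    out = ndimage.convolve1d(img, kernel, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kernel, axis=1, mode="reflect")


def atrous_decompose(img: np.ndarray, levels: int) -> tuple[list[np.ndarray], np.ndarray]:
    """B3-spline à-trous decomposition.

    Returns ``(details, approximation)`` where ``details[l]`` is the detail
    plane of level ``l`` (finest first) and the sum of all details plus the
    approximation reconstructs the input exactly.
    """
    details = []
    approx = np.asarray(img, dtype=np.float64)
    for level in range(levels):
        smooth = _atrous_smooth(approx, level)
        details.append(approx - smooth)
        approx = smooth
    return details, approx


def wbns(image, wavelet_resolution_px: float = 3.0, noise_levels: int = 1):
    """Wavelet-based background and noise subtraction.

    Decomposes the image to ``L = ceil(log2(resolution)) + 1`` à-trous
    levels.  The background estimate is the level-L approximation with
    negative values clamped to zero; the noise estimate is the
    sign-symmetrized magnitude of the finest ``noise_levels`` detail levels.
    Output = clip(image − background − noise, 0, ∞).
    """
    plane = _as_plane(image)
    if wavelet_resolution_px < 1:
        raise ValueError("wavelet_resolution_px must be >= 1")
    levels = int(math.ceil(math.log2(wavelet_resolution_px))) + 1
    levels = max(levels, noise_levels)
    details, approx = atrous_decompose(plane, levels)
    background = np.clip(approx, 0.0, None)
    noise = np.zeros_like(plane)
    for detail in details[:noise_levels]:
        noise += np.abs(detail)
    out = np.clip(plane - background - noise, 0.0, None)
    return _wrap(image, out)


def gaussian_smooth(image, sigma: float):
    """Isotropic normalized Gaussian smoothing with reflective boundaries.

    ``sigma`` is the kernel standard deviation in pixels; 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    plane = _as_plane(image)
    if sigma == 0:
        return _wrap(image, plane.copy())
    return _wrap(image, ndimage.gaussian_filter(plane, sigma, mode="reflect"))


def percentile_cut(image, percentile: float):
    """Zero every pixel at or below the given percentile of positive pixels.

    The threshold is the linear-interpolation quantile of the *strictly
    positive* intensities (zeros from masking excluded); survivors are
    pixels strictly above it.  ``percentile=0`` is special-cased to a zero
    threshold so that every positive pixel is retained.

    Returns
    -------
    (image, threshold)
        The cut image and the intensity threshold used.  An image with no
        positive pixels is returned unchanged with threshold 0 and a
        warning.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    plane = _as_plane(image)
    positives = plane[plane > 0]
    if positives.size == 0:
        warnings.warn("percentile_cut: image has no positive pixels",
                      stacklevel=2)
        return _wrap(image, plane.copy()), 0.0
    if percentile == 0:
        threshold = 0.0
    else:
        threshold = float(np.percentile(positives, percentile))
    out = np.where(plane > threshold, plane, 0.0)
    if threshold > 0 and not out.any():
        # Degenerate case: the threshold reached the maximum (e.g. all
        # positives equal), and a strict cut would empty the image.  The
        # brightest pixels always survive a percentile below 100.
        out = np.where(plane >= positives.max(), plane, 0.0)
    return _wrap(image, out), threshold


def preprocess_channel(image, params: PreprocessParams):
    """Full de-noising chain: wbns → gaussian_smooth → percentile_cut.

    Masking happens upstream (:func:`spotcoloc.segmentation.apply_mask`).
    Returns ``(image, threshold)`` like :func:`percentile_cut`.
    """
    out = wbns(image, params.wavelet_resolution_px, params.noise_levels)
    out = gaussian_smooth(out, params.sigma)
    return percentile_cut(out, params.percentile)
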