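"""Sobel and Canny edge detectors for thousand-pixel grids.

Camera-grade detectors serve as the comparison point for the prosthesis
rule.  Both operate at the prosthesis resolutions (tens of pixels per
side), so the implementation choices lean conservative: replicate-edge
padding (no fabricated border gradients on tiny grids) and the textbook
4-sector non-maximum suppression without sub-pixel interpolation.

Neither detector's parameters come from published values; the defaults
here express thresholds as fractions of the maximum observed gradient
magnitude so they adapt to image contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ActivationMap, GrayImage

__all__ = ["CannyParams", "sobel_detect", "sobel_magnitude", "canny_detect"]

# standard 3x3 kernels; Gx responds to left-to-right brightening
_SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_GY = _SOBEL_GX.T


@dataclass(frozen=True)
class CannyParams:
    """Canny stage parameters.

    Thresholds are fractions of the maximum gradient magnitude of the
    smoothed image when ``relative=True`` (default), else absolute
    gradient-magnitude units.
    """

    gaussian_sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2
    truncate: float = 4.0
    relative: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if not (0 < self.low_threshold <= self.high_threshold):
            raise ValueError("need 0 < low_threshold <= high_threshold")


def _as_array(image) -> np.ndarray:
    arr = image.values if hasattr(image, "values") else np.asarray(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    return arr.astype(np.float64)


def sobel_magnitude(image: GrayImage | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(magnitude, gx, gy) from 3x3 Sobel convolution, replicate padding."""
    arr = _as_array(image)
    gx = ndimage.correlate(arr, _SOBEL_GX, mode="nearest")
    gy = ndimage.correlate(arr, _SOBEL_GY, mode="nearest")
    return np.hypot(gx, gy), gx, gy


def sobel_detect(
    image: GrayImage | np.ndarray,
    threshold: float | None = None,
    threshold_frac: float = 0.25,
) -> ActivationMap:
    """Threshold the Sobel gradient magnitude.

    With ``threshold=None`` the cut is ``threshold_frac`` of the maximum
    observed magnitude (contrast-adaptive default).
    """
    mag, _, _ = sobel_magnitude(image)
    if threshold is None:
        threshold = threshold_frac * float(mag.max())
    return ActivationMap(mag > threshold)


def _nms(mag: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Non-maximum suppression with direction quantized to 4 sectors."""
    h, w = mag.shape
    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    # sector -> the two neighbor offsets perpendicular to the edge
    keep = np.zeros_like(mag, dtype=bool)
    padded = np.pad(mag, 1, mode="constant")  # border neighbors count as 0
    for lo, hi, (dr, dc) in [
        (0.0, 22.5, (0, 1)),      # horizontal gradient -> compare left/right
        (157.5, 180.0, (0, 1)),
        (22.5, 67.5, (1, 1)),     # diagonal
        (67.5, 112.5, (1, 0)),    # vertical gradient -> compare up/down
        (112.5, 157.5, (1, -1)),  # anti-diagonal
    ]:
        sector = (angle >= lo) & (angle < hi)
        n1 = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        n2 = padded[1 - dr : 1 - dr + h, 1 - dc : 1 - dc + w]
        # strict on one side breaks plateau ties to a single-pixel line
        keep |= sector & (mag > n1) & (mag >= n2)
    return keep & (mag > 0)


def canny_detect(image: GrayImage | np.ndarray, params: CannyParams | None = None) -> ActivationMap:
    """Four-stage Canny: Gaussian smoothing, Sobel gradients, 4-sector
    non-maximum suppression, double-threshold hysteresis keeping weak
    pixels 8-connected to strong ones."""
    if params is None:
        params = CannyParams()
    arr = _as_array(image)
    smoothed = ndimage.gaussian_filter(arr, params.gaussian_sigma, mode="nearest",
                                       truncate=params.truncate)
    mag, gx, gy = sobel_magnitude(smoothed)
    thin = _nms(mag, gx, gy)
    if params.relative:
        peak = float(mag.max())
        low = params.low_threshold * peak
        high = params.high_threshold * peak
    else:
        low, high = params.low_threshold, params.high_threshold
    strong = thin & (mag > high)
    weak = thin & (mag > low)
    labels, _ = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    kept = np.unique(labels[strong])
    return ActivationMap(weak & np.isin(labels, kept[kept > 0]))
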