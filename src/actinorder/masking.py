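"""Actin mask by ratio-to-smoothed thresholding.

Dividing the raw intensity by a heavily smoothed copy of itself gives a
local-contrast image that is > 1 on locally actin-rich structures and < 1 in
their vicinity, independent of absolute brightness.  Thresholding near 1
keeps the actin bands and, at the banded stages, discards the dim M-lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = ["ActinMask", "compute_actin_mask"]


@dataclass
class ActinMask:
    """Binary actin mask plus the parameters that produced it.

    ``roi`` is an optional polygon ((x, y) vertices in micrometres); the mask
    is False everywhere outside it.
    """

    mask: np.ndarray
    smoothing_scale: float  # um
    threshold: float
    roi: np.ndarray | None = None


def compute_actin_mask(
    intensity: np.ndarray,
    roi: np.ndarray | None = None,
    smoothing_scale: float = 2.0,
    threshold: float = 1.0,
    pixel_size: float = 154.0,
) -> ActinMask:
    """Threshold the ratio of the image to its Gaussian-smoothed version.

    Parameters
    ----------
    intensity:
        Non-negative 2-D image (typically the total intensity a0).
    roi:
        Optional (N, 2) polygon of (x, y) vertices in micrometres restricting
        the mask; default full frame.
    smoothing_scale:
        Gaussian sigma in micrometres (must exceed the pixel size); 2 um
        spans several sarcomere half-periods so bands stand out against
        their local surround.
    threshold:
        Ratio cut; pixels with intensity/smoothed > threshold are kept
        (strict inequality, so a constant image yields an empty mask at 1.0).
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2:
        raise ValueError("intensity must be 2-D")
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    if smoothing_scale * 1000.0 <= pixel_size:
        raise ValueError("smoothing_scale must exceed the pixel size")
    sigma_px = smoothing_scale * 1000.0 / pixel_size
    smoothed = ndimage.gaussian_filter(intensity, sigma=sigma_px)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(smoothed > 0, intensity / smoothed, 0.0)
    mask = ratio > threshold
    if roi is not None:
        roi = np.asarray(roi, dtype=float)
        if roi.ndim != 2 or roi.shape[1] != 2 or roi.shape[0] < 3:
            raise ValueError("roi must be an (N>=3, 2) polygon of (x, y) um vertices")
        h, w = intensity.shape
        xmax = (w - 1) * pixel_size / 1000.0
        ymax = (h - 1) * pixel_size / 1000.0
        if (
            np.any(roi[:, 0] < 0) or np.any(roi[:, 0] > xmax)
            or np.any(roi[:, 1] < 0) or np.any(roi[:, 1] > ymax)
        ):
            raise ValueError("roi polygon extends outside the image")
        verts_rc = np.column_stack([roi[:, 1], roi[:, 0]]) * 1000.0 / pixel_size
        mask &= polygon2mask(intensity.shape, verts_rc)
    return ActinMask(mask=mask, smoothing_scale=smoothing_scale, threshold=threshold, roi=roi)
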