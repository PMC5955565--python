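"""Averaged sarcomere maps, order profiles, and sarcomere length.

Selected sarcomere objects are rotated onto a common frame (major axis
horizontal, Z-disc at the centre), resampled bilinearly, and averaged
pixelwise; a 1-pixel line through the centre gives the averaged sarcomere
profile.  Sarcomere length is measured independently as the spacing of
intensity peaks along a myofibril line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .polarimetry import OrderMaps
from .segmentation import SarcomereObject

__all__ = [
    "AveragedSarcomereMap",
    "SarcomereProfile",
    "SarcomereLengthResult",
    "average_sarcomere_maps",
    "extract_profile",
    "measure_sarcomere_length",
    "render_orientation_sticks",
]


@dataclass
class AveragedSarcomereMap:
    """Pixelwise average of aligned sarcomere neighbourhoods.

    Odd-sized grids (a centre pixel exists) with the Z-disc at the centre and
    M-lines towards the horizontal edges; rho is stored in the rotated frame
    (0 deg = sarcomere axis) and was averaged axially.
    """

    intensity: np.ndarray
    psi: np.ndarray
    rho: np.ndarray
    n_averaged: int
    pixel_size: float  # nm


@dataclass
class SarcomereProfile:
    """Central 1-pixel line of an averaged sarcomere map."""

    position: np.ndarray  # um, 0 at the Z-disc
    intensity: np.ndarray
    psi: np.ndarray
    rho: np.ndarray
    reference_offset: float = 0.0


@dataclass
class SarcomereLengthResult:
    """Peak-spacing sarcomere lengths pooled over myofibril lines (um).

    ``lengths`` are parabolically refined peak spacings; ``raw_lengths`` the
    unrefined grid spacings.  ``per_line`` holds each line's mean (NaN where
    a line had fewer than two peaks); pupa-level mean/SD/CV pool all
    spacings.
    """

    lengths: list[float]
    raw_lengths: list[float]
    per_line: list[float]
    line_errors: list[bool]
    mean: float
    sd: float
    cv_percent: float


def _sample_bilinear(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(image, [rows, cols], order=1, mode="nearest")


def average_sarcomere_maps(
    order: OrderMaps,
    intensity: np.ndarray,
    selected: list[SarcomereObject],
    extent_px: int | None = None,
) -> AveragedSarcomereMap:
    """Align selected sarcomeres (axis horizontal, centroid centred) and average.

    Each object's neighbourhood is rotated by minus its orientation and
    resampled bilinearly onto a common odd-sized grid; psi and intensity are
    averaged pixelwise, rho is carried along with the rotation
    (rho -> rho - orientation mod 180) and averaged axially via doubled
    angles.  Grid extent defaults to 1.5x the median object major axis.
    """
    if not selected:
        raise ValueError("no sarcomere objects selected for averaging")
    px_um = order.pixel_size / 1000.0
    if extent_px is None:
        median_major = float(np.median([o.major_axis for o in selected]))
        extent_px = int(round(1.5 * median_major / px_um))
    extent_px = max(extent_px, 3)
    if extent_px % 2 == 0:
        extent_px += 1
    c = extent_px // 2
    jj, ii = np.meshgrid(np.arange(extent_px) - c, np.arange(extent_px) - c)
    # output u along the (horizontalized) sarcomere axis, v across it
    u = jj.astype(float)
    v = ii.astype(float)

    cos2 = np.cos(2 * np.deg2rad(order.rho))
    sin2 = np.sin(2 * np.deg2rad(order.rho))
    valid = order.valid.astype(float)

    sums = {k: np.zeros((extent_px, extent_px)) for k in ("int", "psi", "c2", "s2", "w")}
    for obj in selected:
        th = np.deg2rad(obj.orientation)
        cx = obj.centroid[0] / px_um
        cy = obj.centroid[1] / px_um
        cols = cx + u * np.cos(th) - v * np.sin(th)
        rows = cy + u * np.sin(th) + v * np.cos(th)
        w = _sample_bilinear(valid, rows, cols)
        sums["int"] += _sample_bilinear(intensity, rows, cols) * w
        sums["psi"] += _sample_bilinear(order.psi, rows, cols) * w
        c2 = _sample_bilinear(cos2, rows, cols)
        s2 = _sample_bilinear(sin2, rows, cols)
        # rotate the doubled angle into the object frame: rho' = rho - theta
        sums["c2"] += (c2 * np.cos(2 * th) + s2 * np.sin(2 * th)) * w
        sums["s2"] += (s2 * np.cos(2 * th) - c2 * np.sin(2 * th)) * w
        sums["w"] += w

    w = np.where(sums["w"] > 0, sums["w"], np.nan)
    avg_int = sums["int"] / w
    avg_psi = sums["psi"] / w
    avg_rho = np.mod(np.rad2deg(0.5 * np.arctan2(sums["s2"], sums["c2"])), 180.0)
    return AveragedSarcomereMap(
        intensity=avg_int,
        psi=avg_psi,
        rho=avg_rho,
        n_averaged=len(selected),
        pixel_size=order.pixel_size,
    )


def extract_profile(
    amap: AveragedSarcomereMap, reference: float | None = None
) -> SarcomereProfile:
    """1-pixel-thick central line of the averaged map along the sarcomere axis.

    With ``reference`` given, psi is reported relative to it (e.g. the
    minimum of a reference-stage profile), so profiles from different stages
    can be overlaid.
    """
    mid = amap.intensity.shape[0] // 2
    n = amap.intensity.shape[1]
    position = (np.arange(n) - n // 2) * amap.pixel_size / 1000.0
    psi = amap.psi[mid].copy()
    offset = 0.0
    if reference is not None:
        offset = float(reference)
        psi = psi - offset
    return SarcomereProfile(
        position=position,
        intensity=amap.intensity[mid].copy(),
        psi=psi,
        rho=amap.rho[mid].copy(),
        reference_offset=offset,
    )


def _refine_peak(profile: np.ndarray, idx: int) -> float:
    """Sub-sample peak position by a 3-point parabola; falls back to the grid."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def measure_sarcomere_length(
    intensity: np.ndarray,
    lines: list[np.ndarray],
    pixel_size: float = 154.0,
    min_prominence: float = 0.2,
    step_um: float | None = None,
    smooth_um: float = 0.2,
) -> SarcomereLengthResult:
    """Sarcomere lengths from intensity-peak spacing along myofibril lines.

    Each line is an (N, 2) polyline of (x, y) vertices in micrometres drawn
    along one myofibril; intensity is sampled bilinearly at ``step_um``
    (default: half a pixel), local maxima with relative prominence >=
    ``min_prominence`` of the sampled dynamic range are located, and
    consecutive peak spacings are the lengths.  The sampled profile is
    lightly smoothed (Gaussian, ``smooth_um``) before peak detection so that
    shot noise does not jitter sub-pixel peak positions; set 0 to disable.
    Lines yielding fewer than two peaks are flagged and excluded; all
    spacings of one pupa are pooled for the mean/SD/CV.
    """
    px_um = pixel_size / 1000.0
    if step_um is None:
        step_um = px_um / 2.0
    lengths: list[float] = []
    raw_lengths: list[float] = []
    per_line: list[float] = []
    line_errors: list[bool] = []
    for line in lines:
        line = np.asarray(line, dtype=float)
        if line.ndim != 2 or line.shape[1] != 2 or line.shape[0] < 2:
            raise ValueError("each line must be an (N>=2, 2) polyline of (x, y) um")
        seg = np.diff(line, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        total = seglen.sum()
        n_samples = max(int(np.ceil(total / step_um)) + 1, 2)
        s = np.linspace(0.0, total, n_samples)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        x = np.interp(s, cum, line[:, 0])
        y = np.interp(s, cum, line[:, 1])
        prof = _sample_bilinear(intensity, y / px_um, x / px_um)
        ds_line = s[1] - s[0]
        if smooth_um > 0:
            prof = ndimage.gaussian_filter1d(prof, sigma=smooth_um / ds_line)
        dyn = prof.max() - prof.min()
        if dyn <= 0:
            per_line.append(np.nan)
            line_errors.append(True)
            continue
        peaks, _ = signal.find_peaks(prof, prominence=min_prominence * dyn)
        if len(peaks) < 2:
            per_line.append(np.nan)
            line_errors.append(True)
            continue
        ds = s[1] - s[0]
        refined = np.array([_refine_peak(prof, p) for p in peaks]) * ds
        spac = np.diff(refined)
        raw = np.diff(s[peaks])
        lengths.extend(spac.tolist())
        raw_lengths.extend(raw.tolist())
        per_line.append(float(spac.mean()))
        line_errors.append(False)
    if lengths:
        arr = np.asarray(lengths)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        cv = 100.0 * sd / mean if mean > 0 else np.nan
    else:
        mean = sd = cv = np.nan
    return SarcomereLengthResult(
        lengths=lengths,
        raw_lengths=raw_lengths,
        per_line=per_line,
        line_errors=line_errors,
        mean=mean,
        sd=sd,
        cv_percent=cv,
    )


def render_orientation_sticks(
    amap: AveragedSarcomereMap, amplification: float = 50.0, stride: int = 1
) -> pd.DataFrame:
    """Stick field visualizing tiny rho deviations from the sarcomere axis.

    Display angle = amplification x signed deviation of rho from horizontal
    (the deviations inside a sarcomere are fractions of a degree, hence the
    conventional 50x amplification).  Returns a table of (x_um, y_um,
    deviation_deg, display_angle_deg); export only, no analysis reads it.
    """
    if amplification <= 0:
        raise ValueError("amplification must be positive")
    px_um = amap.pixel_size / 1000.0
    h, w = amap.rho.shape
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    deviation = (amap.rho[rr, cc] + 90.0) % 180.0 - 90.0  # signed, in (-90, 90]
    return pd.DataFrame(
        {
            "x_um": (cc.ravel() * px_um),
            "y_um": (rr.ravel() * px_um),
            "deviation_deg": deviation.ravel(),
            "display_angle_deg": amplification * deviation.ravel(),
        }
    )
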