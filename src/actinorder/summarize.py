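"""Hierarchical molecular-order summaries and circular orientation statistics.

The molecular order angle psi is averaged over masked pixels per image,
images are averaged per hemithorax (10-20 images each in the original
acquisitions), and hemithoraxes per population; disorder is reported as
DeltaPsi = Psi - Psi_ref against the mature 90-h APF reference
(Psi_ref = 129 deg by default).  Local orientation variability is the
windowed axial circular SD of rho; orientation angles are 180-deg periodic,
so all dispersion statistics double the angles first and are wrap-safe by
construction.  Group comparisons delegate to the standard nonparametric
tests (Mann-Whitney U unpaired, Wilcoxon signed-rank paired).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .masking import ActinMask
from .polarimetry import OrderMaps

__all__ = [
    "OrderSummary",
    "RhoVariabilityResult",
    "image_mean_psi",
    "summarize_order",
    "axial_circular_sd",
    "rho_variability",
    "longitudinal_order_profile",
    "compare_groups",
    "PSI_REF_DEFAULT",
]

logger = logging.getLogger(__name__)

PSI_REF_DEFAULT = 129.0  # deg, mature 90-h APF reference order angle


@dataclass
class OrderSummary:
    """Image -> hemithorax -> population means of psi and DeltaPsi.

    ``per_image`` and ``per_hemithorax`` are tables with psi and
    delta_psi columns; the population mean is the plain mean of hemithorax
    means and its SD the dispersion across hemithoraxes.
    """

    per_image: pd.DataFrame
    per_hemithorax: pd.DataFrame
    population_mean: float
    population_sd: float
    psi_ref: float

    @property
    def delta_psi(self) -> float:
        return self.population_mean - self.psi_ref


@dataclass
class RhoVariabilityResult:
    """Windowed axial circular SD of rho (degrees)."""

    sd_map: np.ndarray  # NaN outside the mask or where < 2 neighbours
    per_image_mean: float
    window: int


def image_mean_psi(
    order: OrderMaps,
    mask: ActinMask,
    intensity: np.ndarray | None = None,
) -> float:
    """Mean psi over masked valid pixels of one image (NaN if mask empty).

    Unweighted by default; pass ``intensity`` for an intensity-weighted mean.
    """
    sel = mask.mask & order.valid
    if not np.any(sel):
        return np.nan
    if intensity is None:
        return float(order.psi[sel].mean())
    w = np.asarray(intensity, dtype=float)[sel]
    return float(np.average(order.psi[sel], weights=w))


def summarize_order(
    images: list[tuple[OrderMaps, ActinMask]],
    hemithorax: list[str],
    psi_ref: float = PSI_REF_DEFAULT,
    intensity_weights: list[np.ndarray] | None = None,
) -> OrderSummary:
    """Aggregate per-image masked psi means up the acquisition hierarchy.

    ``hemithorax[i]`` labels the hemithorax of image i.  Images with an empty
    mask are excluded with a warning.  Plain (unweighted) means are taken at
    every level, so the population mean equals the mean of hemithorax means.
    """
    if len(images) != len(hemithorax):
        raise ValueError("one hemithorax label per image is required")
    rows = []
    for i, (order, mask) in enumerate(images):
        w = intensity_weights[i] if intensity_weights is not None else None
        psi = image_mean_psi(order, mask, intensity=w)
        if np.isnan(psi):
            logger.warning("image %d has an empty mask; excluded from the summary", i)
            continue
        rows.append({"image": i, "hemithorax": hemithorax[i], "psi": psi})
    if not rows:
        raise ValueError("no image produced a valid masked psi mean")
    per_image = pd.DataFrame(rows)
    per_image["delta_psi"] = per_image["psi"] - psi_ref
    per_hemi = (
        per_image.groupby("hemithorax", sort=True)
        .agg(psi=("psi", "mean"), n_images=("psi", "size"))
        .reset_index()
    )
    per_hemi["delta_psi"] = per_hemi["psi"] - psi_ref
    pop_mean = float(per_hemi["psi"].mean())
    pop_sd = float(per_hemi["psi"].std(ddof=1)) if len(per_hemi) > 1 else 0.0
    return OrderSummary(
        per_image=per_image,
        per_hemithorax=per_hemi,
        population_mean=pop_mean,
        population_sd=pop_sd,
        psi_ref=psi_ref,
    )


def axial_circular_sd(rho_deg: np.ndarray) -> float:
    """Axial circular SD (degrees) of a sample of 180-deg-periodic angles.

    Angles are doubled, the circular SD sqrt(-2 ln Rbar) of the doubled
    angles is taken, and the result halved — so a field mixing 1 and 179 deg
    (the same axis) has a small SD, not ~89 deg.
    """
    rho2 = 2.0 * np.deg2rad(np.asarray(rho_deg, dtype=float).ravel())
    c = np.cos(rho2).mean()
    s = np.sin(rho2).mean()
    rbar = min(np.hypot(c, s), 1.0)
    if rbar <= 0:
        return np.inf
    return float(np.rad2deg(0.5 * np.sqrt(-2.0 * np.log(rbar))))


def rho_variability(
    order: OrderMaps, mask: ActinMask, window: int = 65
) -> RhoVariabilityResult:
    """Local axial circular SD of rho over a centred square window.

    For every masked pixel, the masked neighbours within a ``window`` x
    ``window`` box (65 px ~ 10 um at the default pixel pitch) contribute to
    an axial circular SD; pixels with fewer than two masked neighbours are
    excluded.  The per-image value is the mean over contributing pixels.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    sel = (mask.mask & order.valid).astype(float)
    rho2 = 2.0 * np.deg2rad(order.rho)
    size = (window, window)
    area = window * window
    # windowed sums via mean filters (zero-padded borders)
    n = ndimage.uniform_filter(sel, size=size, mode="constant") * area
    c = ndimage.uniform_filter(np.cos(rho2) * sel, size=size, mode="constant") * area
    s = ndimage.uniform_filter(np.sin(rho2) * sel, size=size, mode="constant") * area
    with np.errstate(divide="ignore", invalid="ignore"):
        rbar = np.clip(np.hypot(c, s) / n, None, 1.0)
        # filter round-off leaves rbar a few ulp below 1 on constant fields;
        # snap so those report an SD of exactly 0
        rbar = np.where(rbar > 1.0 - 1e-12, 1.0, rbar)
        sd = np.rad2deg(0.5 * np.sqrt(-2.0 * np.log(rbar)))
    good = (sel > 0) & (n >= 2) & np.isfinite(sd)
    sd_map = np.where(good, sd, np.nan)
    per_image = float(np.nanmean(sd_map)) if np.any(good) else np.nan
    return RhoVariabilityResult(sd_map=sd_map, per_image_mean=per_image, window=window)


def longitudinal_order_profile(
    order: OrderMaps,
    mask: ActinMask,
    lines: list[np.ndarray],
    bin_um: float = 2.0,
    relative: bool = True,
) -> list[pd.DataFrame]:
    """Binned psi along fibre-length lines, relative to the per-pupa mean.

    Each line is an (N, 2) polyline of (x, y) um from one muscle-fibre end to
    the other.  psi is collected from masked valid pixels nearest to densely
    sampled points along the line, averaged in ``bin_um`` bins of arc length;
    empty bins are linearly interpolated and flagged.  With ``relative``,
    profiles are reported as deviations from the mean over all bins of all
    lines (one pupa), matching the way end-to-end flatness is assessed.
    """
    px_um = order.pixel_size / 1000.0
    sel = mask.mask & order.valid
    h, w = order.psi.shape
    tables = []
    for line in lines:
        line = np.asarray(line, dtype=float)
        seg = np.diff(line, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        total = seglen.sum()
        n_samples = max(int(np.ceil(total / (px_um / 2.0))) + 1, 2)
        s = np.linspace(0.0, total, n_samples)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        x = np.interp(s, cum, line[:, 0])
        y = np.interp(s, cum, line[:, 1])
        rows = np.clip(np.round(y / px_um).astype(int), 0, h - 1)
        cols = np.clip(np.round(x / px_um).astype(int), 0, w - 1)
        ok = sel[rows, cols]
        psi = order.psi[rows, cols]
        edges = np.arange(0.0, total + bin_um, bin_um)
        idx = np.clip(np.digitize(s, edges) - 1, 0, len(edges) - 2)
        n_bins = len(edges) - 1
        means = np.full(n_bins, np.nan)
        for b in range(n_bins):
            in_bin = (idx == b) & ok
            if np.any(in_bin):
                means[b] = psi[in_bin].mean()
        empty = np.isnan(means)
        if np.any(empty) and not np.all(empty):
            filled = np.flatnonzero(~empty)
            means[empty] = np.interp(np.flatnonzero(empty), filled, means[filled])
        centers = 0.5 * (edges[:-1] + edges[1:])
        tables.append(
            pd.DataFrame({"position_um": centers, "psi": means, "interpolated": empty})
        )
    if relative and tables:
        pupa_mean = np.nanmean(np.concatenate([t["psi"].to_numpy() for t in tables]))
        for t in tables:
            t["psi_rel"] = t["psi"] - pupa_mean
    return tables


def compare_groups(
    values_by_group: dict[str, list[float]], paired: bool = False
) -> dict:
    """Two-group nonparametric comparison of per-pupa summary values.

    Unpaired: two-sided Mann-Whitney U; paired: two-sided Wilcoxon
    signed-rank.  Groups with fewer than 3 values are reported as
    underpowered with no p-value.  No multiple-testing correction is applied.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups are required")
    (name_a, a), (name_b, b) = values_by_group.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    report = {
        "groups": [name_a, name_b],
        "n": [int(a.size), int(b.size)],
        "paired": paired,
        "test": "wilcoxon_signed_rank" if paired else "mann_whitney_u",
    }
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        if a.size < 3:
            report.update(underpowered=True, statistic=None, p_value=None)
            return report
        diff = a - b
        if np.all(diff == 0):
            # zero differences: the signed-rank statistic is undefined; report
            # the maximal (no-evidence) p-value by convention
            report.update(underpowered=False, statistic=0.0, p_value=1.0, zero_differences=True)
            return report
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        if a.size < 3 or b.size < 3:
            report.update(underpowered=True, statistic=None, p_value=None)
            return report
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    report.update(
        underpowered=False, statistic=float(res.statistic), p_value=float(res.pvalue)
    )
    return report
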