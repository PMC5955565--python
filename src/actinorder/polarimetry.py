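"""Per-pixel polarimetric inversion: from a polarization stack to (rho, psi) maps.

A stack of fluorescence images acquired under a rotating linear excitation
polarization carries, at every pixel, a second-harmonic modulation

    I(alpha) = a0/K * (1 + a2 cos 2*alpha + b2 sin 2*alpha)

whose amplitude and phase encode the mean in-plane dipole orientation ``rho``
and the total aperture ``psi`` of the angular cone the dipoles explore.
``psi`` is the "molecular order angle": 180 deg means fully isotropic dipoles,
small values mean tight alignment.  Under the uniform-filled in-plane cone
model the modulation depth is the closed form ``sin(psi)/psi`` (psi in
radians, total aperture), which is strictly decreasing and therefore
invertible by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarizationStack",
    "ModulationCoefficients",
    "OrderMaps",
    "DistortionCalibration",
    "compute_modulation_coefficients",
    "harmonic_least_squares",
    "cone_modulation",
    "cone_modulation_3d",
    "invert_cone_psi",
    "invert_cone_model",
    "compensate_distortion",
]

_BISECTION_ITER = 80  # halves (0, pi]; final bracket ~ 1e-24 rad


def _as_angle_array(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1:
        raise ValueError("angles must be a 1-D sequence of degrees")
    return a


def _check_angles(angles: np.ndarray) -> None:
    if len(np.unique(np.round(np.mod(angles, 180.0), 9))) < 3:
        raise ValueError("need at least 3 distinct polarization angles modulo 180 deg")


@dataclass(frozen=True)
class PolarizationStack:
    """K registered intensity images, one per excitation polarization angle.

    Parameters
    ----------
    data:
        Array of shape (K, H, W), non-negative photon counts (or a.u.).
    angles:
        K polarization angles alpha_k in degrees, measured from the image
        x-axis (columns).
    pixel_size:
        Pixel pitch in nanometres.
    """

    data: np.ndarray
    angles: np.ndarray
    pixel_size: float = 154.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        angles = _as_angle_array(self.angles)
        if data.ndim != 3:
            raise ValueError("stack data must have shape (K, H, W)")
        if data.shape[0] != angles.shape[0]:
            raise ValueError(
                f"page count {data.shape[0]} does not match angle count {angles.shape[0]}"
            )
        _check_angles(angles)
        if not np.all(np.isfinite(data)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(data < 0):
            raise ValueError("stack contains negative intensities")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "angles", angles)

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class ModulationCoefficients:
    """Second-harmonic decomposition of I(alpha) at every pixel.

    ``a0`` is the total intensity summed over angles; ``a2``/``b2`` are the
    normalized cos/sin modulation coefficients.  ``valid`` is False where the
    total intensity fell below the floor.  The angle grid is retained so that
    distortion compensation can re-fit without the raw stack.
    """

    a0: np.ndarray
    a2: np.ndarray
    b2: np.ndarray
    valid: np.ndarray
    angles: np.ndarray = field(default=None)


@dataclass
class OrderMaps:
    """Per-pixel mean orientation ``rho`` (deg, axial, [0, 180)) and cone
    aperture ``psi`` (deg, (0, 180]).

    ``clipped`` marks pixels where the measured modulation amplitude exceeded
    1 (possible under noise) and was clamped before inversion.  Isotropic
    pixels (zero modulation) carry psi = 180 and rho = 0 by convention.
    """

    rho: np.ndarray
    psi: np.ndarray
    valid: np.ndarray
    clipped: np.ndarray
    pixel_size: float = 154.0


@dataclass(frozen=True)
class DistortionCalibration:
    """Per-angle polarization distortion of the excitation path.

    ``gains`` is a multiplicative per-angle intensity gain (diattenuation
    proxy); ``ellipticity`` scales the modulated term only (residual
    ellipticity reduces modulation contrast).  The identity calibration
    leaves the forward model unchanged.
    """

    gains: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.gains, dtype=float))
        e = np.atleast_1d(np.asarray(self.ellipticity, dtype=float))
        if g.shape != e.shape or g.ndim != 1:
            raise ValueError("gains and ellipticity must be 1-D arrays of equal length")
        if np.any(g <= 0):
            raise ValueError("distortion gains must be positive")
        object.__setattr__(self, "gains", g)
        object.__setattr__(self, "ellipticity", e)

    @classmethod
    def identity(cls, n_angles: int) -> "DistortionCalibration":
        return cls(np.ones(n_angles), np.ones(n_angles))

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.gains, 1.0) and np.allclose(self.ellipticity, 1.0))


def is_uniform_grid(angles, tol: float = 1e-9) -> bool:
    """True if the angles uniformly tile [0, 180) (any rotation, any order)."""
    a = np.sort(np.mod(_as_angle_array(angles), 180.0))
    k = len(a)
    if k < 3:
        return False
    step = 180.0 / k
    return bool(np.allclose(a - a[0], np.arange(k) * step, atol=tol))


def compute_modulation_coefficients(
    stack: PolarizationStack,
    intensity_floor: float | None = None,
) -> ModulationCoefficients:
    """Decompose I(alpha_k) into (a0, a2, b2) at every pixel.

    On uniform angle grids the discrete sums

        a0 = sum_k I_k,  a2 = 2/a0 sum_k I_k cos 2 alpha_k,
        b2 = 2/a0 sum_k I_k sin 2 alpha_k

    are used; on non-uniform grids these sums are biased and a general linear
    least-squares harmonic fit is applied instead (identical on uniform
    grids).  Pixels whose total intensity is below ``intensity_floor``
    (default: 1% of the per-image maximum a0) are flagged invalid.
    """
    rad2 = 2.0 * np.deg2rad(stack.angles)
    data = stack.data
    a0 = data.sum(axis=0)
    if is_uniform_grid(stack.angles):
        sc = np.tensordot(np.cos(rad2), data, axes=(0, 0))
        ss = np.tensordot(np.sin(rad2), data, axes=(0, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            a2 = np.where(a0 > 0, 2.0 * sc / a0, 0.0)
            b2 = np.where(a0 > 0, 2.0 * ss / a0, 0.0)
    else:
        a0f, a2, b2 = harmonic_least_squares(data, stack.angles)
        a0 = a0f
    if intensity_floor is None:
        intensity_floor = 0.01 * float(a0.max()) if a0.size else 0.0
    valid = a0 >= max(intensity_floor, np.finfo(float).tiny)
    a2 = np.where(valid, a2, 0.0)
    b2 = np.where(valid, b2, 0.0)
    return ModulationCoefficients(a0=a0, a2=a2, b2=b2, valid=valid, angles=stack.angles.copy())


def harmonic_least_squares(data: np.ndarray, angles) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear least-squares fit of A*(1 + a2 cos 2a + b2 sin 2a) per pixel.

    Returns (a0, a2, b2) with a0 = K*A, the total-intensity convention of the
    summation formulas.  Used as the general-grid fallback and as the
    independent cross-check of the summation route.
    """
    angles = _as_angle_array(angles)
    rad2 = 2.0 * np.deg2rad(angles)
    k = len(angles)
    design = np.column_stack([np.ones(k), np.cos(rad2), np.sin(rad2)])
    flat = data.reshape(k, -1)
    params, *_ = np.linalg.lstsq(design, flat, rcond=None)
    p0, p1, p2 = (p.reshape(data.shape[1:]) for p in params)
    with np.errstate(divide="ignore", invalid="ignore"):
        a2 = np.where(p0 != 0, p1 / p0, 0.0)
        b2 = np.where(p0 != 0, p2 / p0, 0.0)
    return k * p0, a2, b2


def cone_modulation(psi):
    """Modulation depth M(psi) of a uniform-filled in-plane cone.

    ``psi`` is the *total* cone aperture in degrees, in (0, 180].  For dipoles
    spread uniformly over [rho - psi/2, rho + psi/2] the cos 2alpha modulation
    contrast is sin(psi)/psi with psi in radians: 1 in the perfectly aligned
    limit, 0 for the isotropic cone (psi = 180 deg).
    """
    arr = np.asarray(psi, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 180):
        raise ValueError("psi must lie in (0, 180] degrees")
    x = np.deg2rad(arr)
    m = np.sin(x) / x
    return m if isinstance(psi, np.ndarray) else float(m)

def cone_modulation_3d(psi, n_quad: int = 256):
    """Numeric modulation depth for a 3-D solid cone of half-angle psi/2.

    Alternative forward kernel: dipoles fill a 3-D cone (uniform solid-angle
    density) whose axis lies in the sample plane; the excitation field is
    in-plane.  Computed by quadrature of <|mu . E(alpha)|^2>; exposed for
    model-sensitivity studies, not used by default.
    """
    arr = np.atleast_1d(np.asarray(psi, dtype=float))
    if np.any(arr <= 0) or np.any(arr > 180):
        raise ValueError("psi must lie in (0, 180] degrees")
    out = np.empty(arr.shape)
    for i, p in np.ndenumerate(arr):
        half = np.deg2rad(p) / 2.0
        # cone axis = x; dipole at polar angle t from axis, azimuth w
        # (midpoint rule: endpoint sampling biases the hemisphere limit)
        t = (np.arange(n_quad) + 0.5) * half / n_quad
        w = np.linspace(0.0, 2 * np.pi, n_quad, endpoint=False)
        tt, ww = np.meshgrid(t, w, indexing="ij")
        mu_x = np.cos(tt)
        mu_y = np.sin(tt) * np.cos(ww)
        weight = np.sin(tt)
        norm = weight.sum()
        if norm == 0:  # psi -> 0 limit
            out[i] = 1.0
            continue
        xx = (mu_x**2 * weight).sum() / norm
        yy = (mu_y**2 * weight).sum() / norm
        # <|mu.E|^2> = xx cos^2 a + yy sin^2 a (+ zz * 0); contrast of cos 2a
        out[i] = (xx - yy) / (xx + yy)
    return out if isinstance(psi, np.ndarray) else float(out[()] if out.ndim == 0 else out[0])


def invert_cone_psi(modulation, kernel: str = "2d") -> np.ndarray:
    """Solve M(psi) = modulation for psi (degrees) by monotone bisection.

    ``modulation`` must lie in [0, 1]; 0 maps to psi = 180 exactly.  The 2-D
    closed-form kernel is bisected directly; the 3-D numeric kernel is
    bisected on a dense monotone tabulation.
    """
    m = np.asarray(modulation, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("modulation must lie in [0, 1]")
    if kernel == "2d":
        lo = np.full(m.shape, 1e-12)
        hi = np.full(m.shape, np.pi)
        for _ in range(_BISECTION_ITER):
            mid = 0.5 * (lo + hi)
            f = np.sin(mid) / mid
            go_right = f > m  # f decreasing: need larger psi
            lo = np.where(go_right, mid, lo)
            hi = np.where(go_right, hi, mid)
        psi = np.rad2deg(0.5 * (lo + hi))
    elif kernel == "3d":
        grid = np.linspace(1e-6, 180.0, 4096)
        table = cone_modulation_3d(grid)
        # table decreasing in psi; interpolate psi(M)
        psi = np.interp(-m, -table, grid)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    psi = np.where(m == 0.0, 180.0, psi)
    return psi if isinstance(modulation, np.ndarray) else float(psi)


def invert_cone_model(coeffs: ModulationCoefficients, kernel: str = "2d") -> OrderMaps:
    """Invert (a2, b2) to per-pixel (rho, psi).

    The modulation amplitude is M_hat = min(sqrt(a2^2 + b2^2), 1) (the clamp
    is flagged in ``clipped``); rho = 1/2 atan2(b2, a2) folded into [0, 180);
    psi solves M(psi) = M_hat by bisection.  Zero modulation yields the
    isotropic result psi = 180 with rho reported as 0.
    """
    amp = np.hypot(coeffs.a2, coeffs.b2)
    clipped = amp > 1.0
    m_hat = np.minimum(amp, 1.0)
    rho = np.mod(np.rad2deg(0.5 * np.arctan2(coeffs.b2, coeffs.a2)), 180.0)
    rho = np.where(m_hat == 0.0, 0.0, rho)
    psi = invert_cone_psi(m_hat, kernel=kernel)
    return OrderMaps(
        rho=rho,
        psi=psi,
        valid=coeffs.valid.copy(),
        clipped=clipped & coeffs.valid,
    )


def compensate_distortion(
    coeffs: ModulationCoefficients, cal: DistortionCalibration
) -> ModulationCoefficients:
    """Remove known per-angle polarization distortions from the coefficients.

    The distorted forward model I_k = g_k * (A + e_k (p1 cos 2a_k + p2 sin
    2a_k)) is linear in (A, p1, p2), and the three measured sums (a0, a2*a0/2,
    b2*a0/2) are linear functionals of I; compensation is therefore an exact
    3x3 linear solve per pixel, equivalent to dividing out g_k and re-fitting
    with the ellipticity-weighted harmonic design.
    """
    if coeffs.angles is None:
        raise ValueError("coefficients carry no angle grid; cannot compensate")
    g = cal.gains
    e = cal.ellipticity
    if g.shape[0] != coeffs.angles.shape[0]:
        raise ValueError("calibration length does not match angle count")
    if cal.is_identity:
        return ModulationCoefficients(
            a0=coeffs.a0.copy(), a2=coeffs.a2.copy(), b2=coeffs.b2.copy(),
            valid=coeffs.valid.copy(), angles=coeffs.angles.copy(),
        )
    rad2 = 2.0 * np.deg2rad(coeffs.angles)
    c, s = np.cos(rad2), np.sin(rad2)
    k = len(coeffs.angles)
    # rows: the three measured functionals of I (sum, sum*cos, sum*sin);
    # columns: the model unknowns (A, p1, p2)
    t = np.array(
        [
            [g.sum(), (g * e * c).sum(), (g * e * s).sum()],
            [(g * c).sum(), (g * e * c * c).sum(), (g * e * c * s).sum()],
            [(g * s).sum(), (g * e * c * s).sum(), (g * e * s * s).sum()],
        ]
    )
    t_inv = np.linalg.inv(t)
    rhs = np.stack([coeffs.a0, 0.5 * coeffs.a2 * coeffs.a0, 0.5 * coeffs.b2 * coeffs.a0])
    params = np.tensordot(t_inv, rhs, axes=(1, 0))
    p0, p1, p2 = params
    with np.errstate(divide="ignore", invalid="ignore"):
        a2 = np.where(p0 != 0, p1 / p0, 0.0)
        b2 = np.where(p0 != 0, p2 / p0, 0.0)
    a0 = k * p0
    valid = coeffs.valid & (p0 > 0)
    return ModulationCoefficients(
        a0=a0, a2=np.where(valid, a2, 0.0), b2=np.where(valid, b2, 0.0),
        valid=valid, angles=coeffs.angles.copy(),
    )
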