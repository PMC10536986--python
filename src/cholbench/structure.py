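"""Structural observables of the bilayer.

Electron density profiles are smoothed with a centered moving mean,
symmetrized, and reduced to the peak-to-peak bilayer thickness; X-ray form
factors are obtained from the density contrast by a cosine Fourier
transform, and their minima positions - the scale-free fingerprint of
bilayer dimensions - are tracked.  Area per phospholipid comes from the
box-area time series with block-averaged errors, and the partial area of
cholesterol follows as the derivative of the leaflet area with respect to
the number of cholesterol molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .interpolate import Curve1D
from .observables import DensityProfile, FormFactorCurve, ValidationError

__all__ = [
    "ApLPoint",
    "smooth_density",
    "symmetrize_density",
    "bilayer_thickness",
    "form_factor",
    "form_factor_minima",
    "area_per_lipid",
    "chol_partial_area",
    "DEFAULT_Q_GRID",
]

logger = logging.getLogger(__name__)

#: Default wave-vector grid for form factors, nm^-1.
DEFAULT_Q_GRID = np.arange(0.01, 10.0 + 1e-12, 0.005)

#: Local density maxima must rise above this fraction of the profile's
#: total range to count as a headgroup peak.
PEAK_PROMINENCE_FRACTION = 0.01


@dataclass
class ApLPoint:
    """Area per phospholipid at one cholesterol concentration.

    ``se`` is the standard error from block averaging of the box-area
    time series.
    """

    chol_pct: float
    apl: float
    se: float
    n_pl_leaflet: int
    box_area_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.apl) and self.apl > 0):
            raise ValidationError("apl must be positive")
        if not (np.isfinite(self.se) and self.se >= 0):
            raise ValidationError("se must be >= 0")


def smooth_density(profile: DensityProfile, window: int = 5) -> DensityProfile:
    """Centered moving-mean smoothing of rho(z).

    At the edges the window shrinks symmetrically (1, 3, 5, ... points),
    so the first and last points are left unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(profile.z):
        raise ValueError("window exceeds profile length")
    half = window // 2
    rho = profile.rho
    out = np.empty_like(rho)
    for i in range(len(rho)):
        k = min(half, i, len(rho) - 1 - i)
        out[i] = rho[i - k : i + k + 1].mean()
    return DensityProfile(profile.z.copy(), out, profile.solvent_rho)


def _require_symmetric_grid(profile: DensityProfile) -> None:
    if abs(profile.z[0] + profile.z[-1]) > 1e-6 * max(1.0, abs(profile.z[-1])):
        raise ValidationError(
            "z grid must be symmetric about the bilayer center at z = 0"
        )


def symmetrize_density(profile: DensityProfile) -> DensityProfile:
    """Average rho(z) with its mirror image rho(-z).

    Bilayers in multilamellar vesicles and the scattering-density-profile
    model are symmetric; leaflet asymmetry beyond numerical noise (> 2 %
    relative) is logged before it is averaged away.
    """
    _require_symmetric_grid(profile)
    mirrored = np.interp(profile.z, -profile.z[::-1], profile.rho[::-1])
    scale = np.max(np.abs(profile.rho)) or 1.0
    asym = np.max(np.abs(profile.rho - mirrored)) / scale
    if asym > 0.02:
        logger.info("leaflet asymmetry of %.1f %% symmetrized away", 100 * asym)
    return DensityProfile(
        profile.z.copy(), 0.5 * (profile.rho + mirrored), profile.solvent_rho
    )


def bilayer_thickness(profile: DensityProfile, smooth: bool = True) -> float:
    """Peak-to-peak bilayer thickness, nm.

    The thickness is twice the distance from the electron density maximum
    (the headgroup peak) to the membrane center: the highest qualifying
    local maximum is located at z > 0 and at z < 0 after smoothing and
    symmetrization, and the thickness is |z+| + |z-|.  A qualifying
    maximum is strictly greater than its neighbors with a prominence of
    at least 1 % of the profile's range; among ties within one grid
    spacing the peak at larger |z| wins.
    """
    if smooth:
        profile = smooth_density(profile)
    profile = symmetrize_density(profile)
    rho = profile.rho
    rng = float(np.ptp(rho))
    if rng <= 0:
        raise ValidationError("no headgroup peak: flat density profile")
    prominence = PEAK_PROMINENCE_FRACTION * rng

    peaks, props = find_peaks(rho, prominence=prominence)
    z = profile.z

    def best_peak(side: np.ndarray) -> float:
        cand = peaks[side[peaks]]
        if len(cand) == 0:
            raise ValidationError("no headgroup peak on one side of the bilayer")
        heights = rho[cand]
        top = heights.max()
        tied = cand[heights >= top - 1e-12]
        return float(z[tied[np.argmax(np.abs(z[tied]))]])

    z_pos = best_peak(z > 0)
    z_neg = best_peak(z < 0)
    return abs(z_pos) + abs(z_neg)


def form_factor(
    profile: DensityProfile, q_grid: np.ndarray | None = None, smooth: bool = False
) -> FormFactorCurve:
    """|F(q)| from the electron density contrast by Fourier transform.

    F(q) = integral of (rho(z) - rho_solvent) cos(qz) dz over the profile
    support, evaluated by trapezoidal quadrature; the magnitude is
    returned.  The profile is symmetrized first, which makes the sine
    part vanish identically.
    """
    _require_symmetric_grid(profile)
    if smooth:
        profile = smooth_density(profile)
    profile = symmetrize_density(profile)
    if q_grid is None:
        q_grid = DEFAULT_Q_GRID
    q_grid = np.asarray(q_grid, float)
    contrast = profile.rho - profile.solvent_rho
    # F(q_i) = sum_j w_j contrast_j cos(q_i z_j), trapezoid weights w_j
    integrand = contrast[None, :] * np.cos(q_grid[:, None] * profile.z[None, :])
    f = trapezoid(integrand, profile.z, axis=1)
    return FormFactorCurve(q_grid, np.abs(f))


def form_factor_minima(ff: FormFactorCurve, n: int = 2) -> list[float]:
    """Positions (nm^-1) of the first ``n`` interior local minima of |F|.

    Each grid minimum is refined by parabolic interpolation through the
    three surrounding points.  A q-grid spacing of <= 0.01 nm^-1 is
    recommended for stable refinement.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    minima_idx, _ = find_peaks(-ff.f_abs)
    if len(minima_idx) < n:
        raise ValidationError(
            f"insufficient minima: found {len(minima_idx)}, need {n}"
        )
    out = []
    for i in sorted(minima_idx)[:n]:
        qm1, q0, qp1 = ff.q[i - 1 : i + 2]
        fm1, f0, fp1 = ff.f_abs[i - 1 : i + 2]
        denom = fm1 - 2 * f0 + fp1
        if denom <= 0:
            out.append(float(q0))
            continue
        # vertex of the parabola through the three points (uniform local grid)
        shift = 0.5 * (fm1 - fp1) / denom
        shift = float(np.clip(shift, -1.0, 1.0))
        out.append(float(q0 + shift * 0.5 * (qp1 - qm1)))
    return out


def area_per_lipid(
    box_area_series: np.ndarray,
    n_pl_leaflet: int,
    n_blocks: int = 5,
    chol_pct: float = 0.0,
) -> ApLPoint:
    """Area per phospholipid from the per-frame box-area series.

    APL is the mean box area divided by the phospholipids per leaflet
    (cholesterol is not counted).  The standard error is estimated by
    block averaging: the series is split into ``n_blocks`` contiguous
    blocks and the standard deviation of the block means is divided by
    sqrt(n_blocks).
    """
    series = np.asarray(box_area_series, float)
    if series.ndim != 1 or len(series) < n_blocks:
        raise ValidationError(
            f"need a 1D series with >= n_blocks={n_blocks} frames"
        )
    if n_pl_leaflet < 1:
        raise ValidationError("n_pl_leaflet must be >= 1")
    if not np.all(np.isfinite(series)):
        raise ValidationError("area series contains NaN or Inf")
    apl = float(series.mean() / n_pl_leaflet)
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = float(means.std(ddof=0) / np.sqrt(n_blocks) / n_pl_leaflet)
    return ApLPoint(chol_pct, apl, se, n_pl_leaflet, series)


def chol_partial_area(
    apl_curve: list[tuple[float, float]], n_pc_leaflet: int
) -> Curve1D:
    """Partial area of cholesterol, nm^2, vs cholesterol mol %.

    The total leaflet area is A_tot(x) = n_pc * APL(x) with x the
    cholesterol mole fraction; the cholesterol count per leaflet is
    N_chol(x) = n_pc * x / (1 - x).  The partial area is the derivative
    dA_tot/dN_chol, evaluated by central finite differences on the
    nonuniform N_chol grid (one-sided at the ends).  A negative partial
    area signals the condensing effect: adding cholesterol shrinks the
    leaflet.
    """
    if len(apl_curve) < 2:
        raise ValidationError("need APL at >= 2 concentrations")
    pts = sorted(apl_curve, key=lambda p: p[0])
    x_pct = np.array([p[0] for p in pts], float)
    apl = np.array([p[1] for p in pts], float)
    if np.any(np.diff(x_pct) <= 0):
        raise ValidationError("duplicate concentrations")
    x = x_pct / 100.0
    if np.any(x >= 1.0):
        raise ValidationError("cholesterol fraction of 1 is singular")
    a_tot = n_pc_leaflet * apl
    n_chol = n_pc_leaflet * x / (1.0 - x)
    partial = np.gradient(a_tot, n_chol)
    return Curve1D(x_pct, partial)
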