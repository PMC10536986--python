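"""Lateral diffusion: MSD analysis and the finite-size (periodic
Saffman-Delbrueck) correction.

A lipid diffusing in a periodically replicated membrane patch drags a 2D
hydrodynamic flow whose periodic images bias the measured diffusion
coefficient D_PBC below its infinite-system value D_inf.  In membrane
hydrodynamics the flow around an inclusion is screened beyond the
Saffman-Delbrueck length L_SD = mu_m*h/(2*mu_f); for simulation boxes with
edge L << L_SD the periodic-image correction is logarithmic in L.  The
box-size dependence implemented here is

    D_PBC(L) = D_inf + (k_B T)/(4 pi mu_m h) *
               [ ln(L / L_SD) - xi - (2 pi / L_SD) * W(L, H) ]

in the limit of infinite interleaflet friction (the two leaflets move as
one sheet).  The first two bracket terms are the periodic correction of a
pure 2D membrane: xi = ln(2 pi^{3/2} / Gamma(3/4)^2) - gamma_E = 1.42647
is the exact square-lattice hydrodynamic constant (the finite part of the
lattice sum of the 2D Oseen kernel, expressible through the Epstein zeta
function of the square lattice).  The last term is the leading correction
from momentum uptake by the two water slabs of half-thickness
H = (L_z - h)/2 that separate the membrane from its periodic images:

    W(L, H) = (1/L^2) * sum_{k != 0} tanh(|k| H) / |k|^3,

summed over the in-plane reciprocal lattice k = 2 pi n / L.  The water
term is a small (<1 %) but systematic reduction whenever membrane momentum
transport dominates (mu_m h >> 2 mu_f H), which holds for all lipid
systems of interest.  Fitting D_PBC(L) measured at several box sizes
yields both D_inf and the membrane shear viscosity mu_m.

Because the correction is logarithmic in L at fixed water content, D_PBC
approaches D_inf only slowly; the model is meant for the fitting regime
L << L_SD and is not a uniform large-L limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import constants
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

from .observables import (
    FiniteSizeSeries,
    MembraneGeometry,
    MSDCurve,
    PBCFitResult,
    ValidationError,
)

__all__ = [
    "XI_SQUARE_LATTICE",
    "PlanarTrajectorySet",
    "compute_msd",
    "fit_msd_linear",
    "saffman_delbrueck_length",
    "dpbc_model",
    "fit_finite_size",
    "mc_error_propagation",
]

#: Hydrodynamic constant of the periodic square lattice,
#: ln(2 pi^{3/2} / Gamma(3/4)^2) - gamma_E.
XI_SQUARE_LATTICE = float(
    np.log(2.0 * np.pi**1.5 / gamma_fn(0.75) ** 2) - np.euler_gamma
)

#: Fitted viscosity is reported as unidentifiable when the finite-size
#: correction explains less than this fraction of the mean D_PBC.
DEGENERACY_THRESHOLD = 0.01

_LATTICE_N = 64  # reciprocal-lattice cutoff for the water-slab sum


@dataclass
class PlanarTrajectorySet:
    """Unwrapped 2D center-of-mass trajectories with leaflet labels.

    ``times`` in ns (uniform step); ``positions`` with shape
    ``(n_particles, n_frames, 2)`` in nm; ``leaflet`` per-particle labels
    from {"upper", "lower"}.
    """

    times: np.ndarray
    positions: np.ndarray
    leaflet: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        self.leaflet = np.asarray(self.leaflet)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValidationError("need >= 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError("time grid must be uniform and increasing")
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValidationError("positions must have shape (P, T, 2)")
        if self.positions.shape[1] != len(self.times):
            raise ValidationError("positions and times disagree on frame count")
        if len(self.leaflet) != self.positions.shape[0]:
            raise ValidationError("one leaflet label per particle required")
        labels = set(np.unique(self.leaflet).tolist())
        if not labels <= {"upper", "lower"}:
            raise ValidationError(
                f"unlabeled or unknown leaflet tags: {sorted(labels - {'upper', 'lower'})}"
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of trajectories x with shape (..., T).

    Uses the FFT autocorrelation decomposition
    MSD(d) = S1(d) - 2*S2(d), cost O(T log T) per series.
    """
    n = x.shape[-1]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft, axis=-1)
    s2 = np.fft.irfft(fx * np.conj(fx), nfft, axis=-1)[..., :n].real
    counts = np.arange(n, 0, -1, dtype=float)
    s2 /= counts

    d = x**2
    # S1(m) = sum_{t=0}^{n-m-1} [d(t) + d(t+m)] / (n-m)
    csum = np.concatenate(
        [np.zeros(d.shape[:-1] + (1,)), np.cumsum(d, axis=-1)], axis=-1
    )
    total = csum[..., -1:]
    m = np.arange(n)
    head = csum[..., n - m] - csum[..., 0:1]  # sum of first n-m terms
    tail = total - csum[..., m]  # sum of last n-m terms
    s1 = (head + tail) / counts
    return s1 - 2.0 * s2


def compute_msd(traj: PlanarTrajectorySet, stride: int = 1) -> MSDCurve:
    """Lateral MSD averaged over particles and all time origins.

    Each leaflet's collective drift - the mean displacement of its member
    particles relative to the first frame - is subtracted from its
    members before the MSD is accumulated, so collective sliding of a
    monolayer does not masquerade as diffusion.  Both leaflets are then
    averaged jointly.  ``stride`` subsamples time origins via frame
    decimation for speed (default uses every origin).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pos = traj.positions[:, ::stride, :]
    times = traj.times[::stride]
    corrected = pos.copy()
    for label in ("upper", "lower"):
        members = traj.leaflet == label
        if not np.any(members):
            continue
        drift = pos[members].mean(axis=0) - pos[members, 0, :].mean(axis=0)
        corrected[members] -= drift[None, :, :]

    x = np.moveaxis(corrected, 1, -1)  # (P, 2, T)
    msd = _msd_fft(x).sum(axis=1).mean(axis=0)  # sum dims, mean particles
    msd = np.maximum(msd, 0.0)
    msd[0] = 0.0
    return MSDCurve(times - times[0], msd)


def fit_msd_linear(
    msd: MSDCurve, window: tuple[float, float] = (10.0, 100.0)
) -> tuple[float, float]:
    """Straight-line fit MSD = 4 D Delta + b inside the lag-time window.

    Returns ``(D, intercept)`` with D in um^2/s (slope in nm^2/ns maps to
    D as slope * 250) and the intercept in nm^2.  The default window of
    10-100 ns excludes both the short-time ballistic/rattling regime and
    the poorly averaged long lags.
    """
    lo, hi = window
    if lo < msd.lag[0] - 1e-9 or hi > msd.lag[-1] + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] ns outside the data support "
            f"[{msd.lag[0]:g}, {msd.lag[-1]:g}] ns"
        )
    sel = (msd.lag >= lo) & (msd.lag <= hi)
    if np.count_nonzero(sel) < 3:
        raise ValueError("need >= 3 MSD points inside the fit window")
    slope, intercept = np.polyfit(msd.lag[sel], msd.msd[sel], 1)
    # slope [nm^2/ns] = 4 D; 1 nm^2/ns = 1000 um^2/s
    return float(slope * 250.0), float(intercept)


def saffman_delbrueck_length(mu_m: float, h: float, mu_f: float) -> float:
    """Saffman-Delbrueck length L_SD = mu_m * h / (2 mu_f), nm."""
    if mu_m <= 0 or h <= 0 or mu_f <= 0:
        raise ValueError("viscosities and thickness must be positive")
    return mu_m * h / (2.0 * mu_f)


@lru_cache(maxsize=1024)
def _water_slab_sum(L: float, H: float, n_max: int = _LATTICE_N) -> float:
    """W(L, H) = (1/L^2) sum'_k tanh(|k| H)/|k|^3 over k = 2 pi n / L, nm.

    Evaluated by direct lattice summation over |n| <= n_max with the
    continuum tail sum_{|n|>n_max} 1/|n|^3 ~ 2 pi / n_max appended
    (tanh ~ 1 there).
    """
    m = np.arange(-n_max, n_max + 1)
    nx, ny = np.meshgrid(m, m, indexing="ij")
    r = np.sqrt(nx * nx + ny * ny)
    mask = (r > 0) & (r <= n_max)
    rn = r[mask]
    c = 2.0 * np.pi * H / L
    s = float(np.sum(np.tanh(c * rn) / rn**3)) + 2.0 * np.pi / n_max
    return L / (8.0 * np.pi**3) * s


def _pbc_correction_bracket(L, mu_m: float, geom: MembraneGeometry):
    """ln(L/L_SD) - xi - (2 pi/L_SD) W(L, H); dimensionless."""
    l_sd = saffman_delbrueck_length(mu_m, geom.h, geom.mu_f)
    L_arr = np.atleast_1d(np.asarray(L, float))
    w = np.array([_water_slab_sum(float(l), geom.H) for l in L_arr])
    return np.log(L_arr / l_sd) - XI_SQUARE_LATTICE - 2.0 * np.pi / l_sd * w


def _thermal_prefactor(mu_m: float, geom: MembraneGeometry) -> float:
    """k_B T / (4 pi mu_m h) in um^2/s (mu_m in mPa s, h in nm)."""
    kT = constants.k * geom.T  # J
    return kT / (4.0 * np.pi * mu_m * 1e-3 * geom.h * 1e-9) * 1e12


def dpbc_model(L, d_inf: float, mu_m: float, geom: MembraneGeometry):
    """Forward model: D_PBC at box edge L for given D_inf and mu_m.

    All lengths in nm, viscosities in mPa s, diffusion in um^2/s.  Scalar
    L returns a scalar.
    """
    if d_inf <= 0 or mu_m <= 0:
        raise ValueError("d_inf and mu_m must be positive")
    L_arr = np.atleast_1d(np.asarray(L, float))
    if np.any(L_arr <= 0):
        raise ValueError("L must be positive")
    out = d_inf + _thermal_prefactor(mu_m, geom) * _pbc_correction_bracket(
        L_arr, mu_m, geom
    )
    return float(out[0]) if np.isscalar(L) or np.ndim(L) == 0 else out


def _fit_core(
    L: np.ndarray,
    d: np.ndarray,
    geom: MembraneGeometry,
    init: tuple[float, float],
) -> tuple[float, float, float]:
    """Least-squares fit of (d_inf, mu_m); returns (d_inf, mu_m, cost)."""

    def residuals(theta):
        d_inf, mu_m = np.exp(theta)
        return (
            d_inf
            + _thermal_prefactor(mu_m, geom) * _pbc_correction_bracket(L, mu_m, geom)
            - d
        )

    res = least_squares(
        residuals,
        x0=np.log(init),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"finite-size fit failed to converge: {res.message}")
    d_inf, mu_m = np.exp(res.x)
    return float(d_inf), float(mu_m), float(res.cost)


def fit_finite_size(
    series: FiniteSizeSeries, init_mu_m: float = 100.0
) -> PBCFitResult:
    """Fit the finite-size model to D_PBC(L), extracting D_inf and mu_m.

    Both parameters are kept positive through a log parameterization.
    When D_PBC is effectively constant across L, the correction term
    carries no information on the membrane viscosity and the result is
    flagged ``degenerate`` instead of reporting a meaningless mu_m.
    """
    L, d = series.L, series.d_pbc
    geom = series.geom
    if np.ptp(d) < 1e-12 * np.mean(d):
        return PBCFitResult(
            d_inf=float(np.mean(d)),
            mu_m=np.nan,
            l_sd=np.nan,
            degenerate=True,
        )
    d_inf, mu_m, _ = _fit_core(L, d, geom, (float(d.max()), init_mu_m))
    correction = _thermal_prefactor(mu_m, geom) * _pbc_correction_bracket(
        L, mu_m, geom
    )
    if np.max(np.abs(correction)) < DEGENERACY_THRESHOLD * np.mean(d):
        return PBCFitResult(
            d_inf=float(np.mean(d)), mu_m=np.nan, l_sd=np.nan, degenerate=True
        )
    return PBCFitResult(
        d_inf=d_inf,
        mu_m=mu_m,
        l_sd=saffman_delbrueck_length(mu_m, geom.h, geom.mu_f),
    )


def _fit_many(
    L: np.ndarray,
    d_matrix: np.ndarray,
    geom: MembraneGeometry,
    theta0: np.ndarray,
    n_iter: int = 60,
) -> np.ndarray:
    """Batched Gauss-Newton fits of (log d_inf, log mu_m) for each row of
    ``d_matrix``; returns ``(n, 2)`` parameters on the linear scale.

    The model and its analytic Jacobian are cheap closed forms, so the
    2x2 normal equations are solved for all replicas simultaneously.
    Step halving guards against overshooting.
    """
    n = d_matrix.shape[0]
    kT_term = constants.k * geom.T / (4.0 * np.pi * 1e-3 * geom.h * 1e-9) * 1e12
    w = np.array([_water_slab_sum(float(l), geom.H) for l in L])
    two_pi_w = 2.0 * np.pi * w
    lsd_per_mu = geom.h / (2.0 * geom.mu_f)  # L_SD = lsd_per_mu * mu_m

    # physical clamps keep runaway replicas finite: a replica whose noise
    # flattens or inverts the D(L) trend drives mu_m toward +inf (the
    # correction-free limit), which is retained as a ceiling sample in the
    # skewed mu_m distribution rather than allowed to overflow
    bounds = np.array([[np.log(1e-6), np.log(1e6)], [np.log(1e-3), np.log(1e9)]])

    def clamp(th):
        return np.clip(th, bounds[:, 0], bounds[:, 1])

    theta = clamp(np.tile(theta0, (n, 1)).astype(float))

    def model_and_jac(th):
        d_inf = np.exp(th[:, 0:1])
        mu_m = np.exp(th[:, 1:2])
        l_sd = lsd_per_mu * mu_m
        pref = kT_term / mu_m
        bracket = (
            np.log(L[None, :] / l_sd) - XI_SQUARE_LATTICE - two_pi_w[None, :] / l_sd
        )
        f = d_inf + pref * bracket
        # d f / d log mu_m = pref * (-bracket - 1 + 2 pi W / L_SD)
        jac_mu = pref * (-bracket - 1.0 + two_pi_w[None, :] / l_sd)
        return f, np.broadcast_to(d_inf, f.shape), jac_mu

    f, j0, j1 = model_and_jac(theta)
    resid = f - d_matrix
    cost = np.sum(resid**2, axis=1)
    for _ in range(n_iter):
        # normal equations J^T J step = -J^T r, batched 2x2
        a00 = np.sum(j0 * j0, axis=1)
        a01 = np.sum(j0 * j1, axis=1)
        a11 = np.sum(j1 * j1, axis=1)
        b0 = -np.sum(j0 * resid, axis=1)
        b1 = -np.sum(j1 * resid, axis=1)
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step = np.stack(
            [(a11 * b0 - a01 * b1) / det, (a00 * b1 - a01 * b0) / det], axis=1
        )
        scale = np.ones((n, 1))
        for _ in range(25):  # step halving where the cost would rise
            trial = clamp(theta + scale * step)
            f, j0_t, j1_t = model_and_jac(trial)
            r_t = f - d_matrix
            c_t = np.sum(r_t**2, axis=1)
            worse = ~(c_t <= cost + 1e-15)  # NaN/Inf trials count as worse
            if not np.any(worse):
                break
            scale[worse] *= 0.5
        theta = clamp(theta + scale * step)
        f, j0, j1 = model_and_jac(theta)
        resid = f - d_matrix
        new_cost = np.sum(resid**2, axis=1)
        if np.all(np.abs(cost - new_cost) <= 1e-14 * (1.0 + cost)):
            cost = new_cost
            break
        cost = new_cost
    return np.exp(theta)


def mc_error_propagation(
    series: FiniteSizeSeries, n: int = 10000, seed: int | None = None
) -> PBCFitResult:
    """Monte-Carlo propagation of D_PBC uncertainties through the fit.

    ``n`` replicas of the series are drawn with each D_PBC perturbed by
    Gaussian noise of its stated error (in practice estimated from the
    difference between the two leaflets), and the finite-size fit is
    repeated on every replica.  The spread of the D_inf sample gives
    ``d_inf_err``; the raw mu_m samples are returned because their
    distribution is often skewed.
    """
    d_err = series.d_err
    if d_err is None:
        raise ValidationError("every point needs d_err for error propagation")
    base = fit_finite_size(series)
    if base.degenerate:
        raise ValidationError("cannot propagate errors through a degenerate fit")
    rng = np.random.default_rng(seed)
    L, d = series.L, series.d_pbc
    perturbed = d[None, :] + rng.standard_normal((n, len(d))) * d_err[None, :]
    theta0 = np.log([base.d_inf, base.mu_m])
    params = _fit_many(L, perturbed, series.geom, theta0)
    d_inf_samples = params[:, 0]
    mu_m_samples = params[:, 1]
    return PBCFitResult(
        d_inf=base.d_inf,
        mu_m=base.mu_m,
        l_sd=base.l_sd,
        d_inf_err=float(np.std(d_inf_samples)),
        mu_m_samples=mu_m_samples,
        d_inf_samples=d_inf_samples,
    )
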