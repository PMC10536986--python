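"""Interpolation of observables over cholesterol concentration and the
deviation engine that turns simulation/experiment pairs into relative
deviation curves.

Observables measured at a handful of cholesterol concentrations are
linearly interpolated onto a dense concentration grid (default 0-46 mol %
in 1 % steps), simulation and experiment surfaces are subtracted, and the
differences are reduced to per-concentration relative deviations in %.
Interpolation is strictly that - queries outside the measured
concentration span are refused rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .observables import ValidationError

__all__ = [
    "DEFAULT_CHOL_GRID",
    "EXPERIMENTAL_OP_BAND",
    "Surface2D",
    "DeviationSurface",
    "Curve1D",
    "build_surface_2d",
    "interp_curve_1d",
    "deviation_surface",
    "relative_deviation_curve",
]

#: Default cholesterol grid, mol %: 0..46 in 1 % steps.
DEFAULT_CHOL_GRID = np.arange(0.0, 47.0, 1.0)

#: Estimated experimental uncertainty of C-H order parameters; deviations
#: within +-0.02 are considered compatible with experiment.
EXPERIMENTAL_OP_BAND = 0.02


class RangeError(ValueError):
    """Raised when a query would require extrapolation."""


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValidationError(f"{name} must be a 1D grid with >= 2 points")
    if not np.all(np.isfinite(grid)):
        raise ValidationError(f"{name} contains NaN or Inf")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError(f"{name} must be strictly increasing")
    return grid


@dataclass
class Surface2D:
    """An observable on a regular (coordinate x cholesterol mol %) grid.

    ``coord`` is the first axis (carbon index or z in nm); ``values`` has
    shape ``(len(coord), len(chol_grid))``.
    """

    coord: np.ndarray
    chol_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.coord = _check_grid(self.coord, "coord")
        self.chol_grid = _check_grid(self.chol_grid, "chol_grid")
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.coord), len(self.chol_grid)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.coord)}, {len(self.chol_grid)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("surface contains NaN or Inf")
        if self.chol_grid[0] < 0 or self.chol_grid[-1] > 46.0 + 1e-9:
            raise ValidationError("chol_grid must lie within [0, 46] mol %")

    def same_grids(self, other: "Surface2D") -> bool:
        return (
            self.coord.shape == other.coord.shape
            and self.chol_grid.shape == other.chol_grid.shape
            and np.allclose(self.coord, other.coord)
            and np.allclose(self.chol_grid, other.chol_grid)
        )


@dataclass
class DeviationSurface(Surface2D):
    """Signed sim - exp difference surface with its within-error mask.

    The sign convention follows the order-parameter maps: negative values
    mean the simulated S_CH is more negative than experiment, i.e. the
    chains are too ordered.  ``mask`` is True where |sim - exp| <= band.
    """

    mask: np.ndarray = None  # type: ignore[assignment]
    band: float = EXPERIMENTAL_OP_BAND

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mask is None:
            self.mask = np.abs(self.values) <= self.band
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape mismatch")


@dataclass
class Curve1D:
    """A scalar observable (or relative deviation, %) vs cholesterol mol %."""

    chol_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.chol_grid = _check_grid(self.chol_grid, "chol_grid")
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.chol_grid.shape:
            raise ValidationError("values must match chol_grid length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("curve contains NaN or Inf")

    def same_grid(self, other: "Curve1D") -> bool:
        return self.chol_grid.shape == other.chol_grid.shape and np.allclose(
            self.chol_grid, other.chol_grid
        )


def _interp_columns(
    x_in: np.ndarray, values_in: np.ndarray, x_out: np.ndarray, what: str
) -> np.ndarray:
    """Linear interpolation along the last axis, refusing extrapolation."""
    if x_out[0] < x_in[0] - 1e-9 or x_out[-1] > x_in[-1] + 1e-9:
        raise RangeError(
            f"{what} grid [{x_out[0]:g}, {x_out[-1]:g}] exceeds the input span "
            f"[{x_in[0]:g}, {x_in[-1]:g}]; interpolation only, never extrapolation"
        )
    x_out = np.clip(x_out, x_in[0], x_in[-1])
    out = np.empty(values_in.shape[:-1] + (len(x_out),))
    for idx in np.ndindex(values_in.shape[:-1]):
        out[idx] = np.interp(x_out, x_in, values_in[idx])
    return out


def build_surface_2d(
    profiles: list[tuple[float, np.ndarray, np.ndarray]],
    chol_grid: np.ndarray = DEFAULT_CHOL_GRID,
    coord_grid: np.ndarray | None = None,
) -> Surface2D:
    """Build a 2D (coordinate x cholesterol) surface by bilinear interpolation.

    Parameters
    ----------
    profiles
        ``(chol_pct, coord_support, values)`` per measured concentration;
        each profile may sit on its own coordinate support.
    chol_grid
        Target concentration grid, mol %; must lie inside the measured
        span (inputs above 46 mol % define the upper hull but queries are
        capped at 46).
    coord_grid
        Target first-axis grid.  Defaults to the intersection of the
        input supports: the span ``[max(min), min(max)]`` sampled on the
        support of the first profile, so that carbons (or z points)
        missing at some concentration are dropped rather than invented.
    """
    if len(profiles) < 2:
        raise ValidationError("need profiles at >= 2 concentrations to interpolate")
    profiles = sorted(profiles, key=lambda p: p[0])
    chol_in = np.array([p[0] for p in profiles], float)
    if np.any(np.diff(chol_in) <= 0):
        raise ValidationError("duplicate input concentrations")
    chol_grid = np.atleast_1d(np.asarray(chol_grid, float))
    if len(chol_grid) > 1:
        chol_grid = _check_grid(chol_grid, "chol_grid")

    supports = [np.asarray(p[1], float) for p in profiles]
    if coord_grid is None:
        lo = max(s[0] for s in supports)
        hi = min(s[-1] for s in supports)
        if hi <= lo:
            raise ValidationError("input coordinate supports do not overlap")
        base = supports[0]
        coord_grid = base[(base >= lo - 1e-12) & (base <= hi + 1e-12)]
        dropped = len(base) - len(coord_grid)
        if dropped:
            warnings.warn(
                f"{dropped} coordinate points outside the common support were "
                "dropped",
                stacklevel=2,
            )
    coord_grid = _check_grid(coord_grid, "coord_grid")

    # resample every profile onto the common coordinate grid, then
    # interpolate linearly along the concentration axis
    resampled = np.empty((len(coord_grid), len(chol_in)))
    for j, (support, (_, _, vals)) in enumerate(zip(supports, profiles)):
        support = _check_grid(support, "profile coordinate support")
        vals = np.asarray(vals, float)
        if vals.shape != support.shape:
            raise ValidationError("profile values must match its support")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("profile contains NaN or Inf")
        resampled[:, j] = _interp_columns(support, vals, coord_grid, "coord")

    values = _interp_columns(chol_in, resampled, chol_grid, "cholesterol")
    return Surface2D(coord_grid, chol_grid, values)


def interp_curve_1d(
    points: list[tuple[float, float]],
    chol_grid: np.ndarray = DEFAULT_CHOL_GRID,
) -> Curve1D:
    """Piecewise-linear interpolation of a scalar observable vs mol % CHOL."""
    if len(points) < 2:
        raise ValidationError("need >= 2 points to interpolate")
    points = sorted(points, key=lambda p: p[0])
    x = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    if np.any(np.diff(x) <= 0):
        raise ValidationError("duplicate input concentrations")
    if not np.all(np.isfinite(y)):
        raise ValidationError("input values contain NaN or Inf")
    chol_grid = np.atleast_1d(np.asarray(chol_grid, float))
    values = _interp_columns(x, y, chol_grid, "cholesterol")
    return Curve1D(chol_grid, values)


def deviation_surface(
    sim: Surface2D, exp: Surface2D, band: float = EXPERIMENTAL_OP_BAND
) -> DeviationSurface:
    """Signed sim - exp difference surface.

    Antisymmetric in its arguments; the companion ``mask`` marks grid
    points whose absolute deviation is within the experimental error band
    (the points drawn white in deviation maps).
    """
    if not sim.same_grids(exp):
        raise ValidationError("sim and exp surfaces must share identical grids")
    diff = sim.values - exp.values
    return DeviationSurface(
        coord=sim.coord.copy(),
        chol_grid=sim.chol_grid.copy(),
        values=diff,
        mask=np.abs(diff) <= band,
        band=band,
    )


def relative_deviation_curve(sim, exp) -> Curve1D:
    """Per-concentration relative deviation of sim from exp, in %.

    For surfaces, the absolute differences are averaged over the first
    axis (carbons, or z) and normalized by the equally averaged |exp| at
    the same concentration; for curves, |sim - exp| / |exp| pointwise.
    Both are multiplied by 100.
    """
    if isinstance(sim, Surface2D) and isinstance(exp, Surface2D):
        if not sim.same_grids(exp):
            raise ValidationError("sim and exp surfaces must share identical grids")
        num = np.mean(np.abs(sim.values - exp.values), axis=0)
        den = np.mean(np.abs(exp.values), axis=0)
        grid = sim.chol_grid
    elif isinstance(sim, Curve1D) and isinstance(exp, Curve1D):
        if not sim.same_grid(exp):
            raise ValidationError("sim and exp curves must share one grid")
        num = np.abs(sim.values - exp.values)
        den = np.abs(exp.values)
        grid = sim.chol_grid
    else:
        raise TypeError("sim and exp must both be Surface2D or both Curve1D")

    zero = den <= 0
    if np.any(zero):
        bad = grid[zero]
        raise ValidationError(
            f"experimental normalizer is zero at {bad.tolist()} mol % CHOL"
        )
    return Curve1D(grid.copy(), 100.0 * num / den)
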