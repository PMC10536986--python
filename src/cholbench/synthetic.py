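"""Synthetic observables with known ground truth.

Every pipeline stage in this package can be exercised without molecular
dynamics trajectories or experimental downloads: the generators below
emulate the *structure* of the real inputs - scattering-density-profile
(SDP) style electron densities built from Gaussians and error functions,
order-parameter profiles with a cholesterol ordering response, planar
Brownian trajectories, and forward-modelled D_PBC(L) series - and return
their ground truth alongside the data, so recovery tests compare against
construction parameters rather than against any fitted quantity.

The generators are structurally, not biophysically, faithful: default
magnitudes are chosen to resemble a POPC bilayer, but no attempt is made
to reproduce real order parameters or densities quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .diffusion import PlanarTrajectorySet, dpbc_model
from .observables import (
    DensityProfile,
    FiniteSizeSeries,
    MembraneGeometry,
    OPEntry,
    OrderParameterSet,
    ValidationError,
)

__all__ = [
    "SDPDensitySpec",
    "OPModelSpec",
    "gen_sdp_density",
    "gen_slab_density",
    "gen_op_profiles",
    "gen_brownian_traj",
    "gen_finite_size_series",
    "default_z_grid",
]

#: Bulk water electron density, e/nm^3.
WATER_RHO = 333.0


def default_z_grid(z_max: float = 4.0, dz: float = 0.02) -> np.ndarray:
    """Symmetric z grid about the bilayer center, nm."""
    n = int(round(z_max / dz))
    return np.linspace(-n * dz, n * dz, 2 * n + 1)


@dataclass
class SDPDensitySpec:
    """Parameters of an SDP-style synthetic electron density.

    The profile is a water plateau joined to a lower acyl-chain plateau
    through error-function edges, plus a Gaussian headgroup peak per
    leaflet at +-z_h and a Gaussian methyl trough at the center:

        rho(z) = rho_w + (rho_c - rho_w) * plateau(z)
                 + A_h [G(z - z_h) + G(z + z_h)] - A_m G_m(z)

    ``z_h`` is the ground-truth headgroup peak position, so the
    peak-to-peak thickness of the generated profile is 2 z_h by
    construction (to within the grid spacing).
    """

    z_h: float = 1.9  # headgroup Gaussian centers, +-nm
    hg_width: float = 0.30  # headgroup Gaussian sigma, nm
    hg_amplitude: float = 130.0  # headgroup Gaussian amplitude, e/nm^3
    methyl_width: float = 0.30  # methyl trough sigma, nm
    methyl_depth: float = 100.0  # methyl trough depth, e/nm^3
    chain_rho: float = 290.0  # acyl chain plateau, e/nm^3
    edge_z: float = 2.4  # erf edge position (chain->water), nm
    edge_width: float = 0.25  # erf edge sigma, nm
    solvent_rho: float = WATER_RHO

    @property
    def thickness(self) -> float:
        """Ground-truth peak-to-peak bilayer thickness, nm."""
        return 2.0 * self.z_h


def gen_sdp_density(
    spec: SDPDensitySpec = SDPDensitySpec(), z_grid: np.ndarray | None = None
) -> tuple[DensityProfile, SDPDensitySpec]:
    """Deterministic SDP-style density profile; returns (profile, truth).

    Raises a spec error when the parameters produce negative densities or
    a profile that does not relax to the solvent density at the edges
    (within 1 %).
    """
    if z_grid is None:
        z_grid = default_z_grid()
    z = np.asarray(z_grid, float)

    def gauss(z0: float, sigma: float) -> np.ndarray:
        return np.exp(-0.5 * ((z - z0) / sigma) ** 2)

    # 1 inside the membrane, 0 in water, erf edges at +-edge_z
    plateau = 0.5 * (
        erf((z + spec.edge_z) / (np.sqrt(2) * spec.edge_width))
        - erf((z - spec.edge_z) / (np.sqrt(2) * spec.edge_width))
    )
    rho = (
        spec.solvent_rho
        + (spec.chain_rho - spec.solvent_rho) * plateau
        + spec.hg_amplitude * (gauss(spec.z_h, spec.hg_width) + gauss(-spec.z_h, spec.hg_width))
        - spec.methyl_depth * gauss(0.0, spec.methyl_width)
    )
    if np.any(rho < 0):
        raise ValidationError("spec produces negative electron densities")
    edge = 0.5 * (rho[0] + rho[-1])
    if abs(edge - spec.solvent_rho) > 0.01 * spec.solvent_rho:
        raise ValidationError(
            "profile does not reach the solvent density at the grid edges; "
            "enlarge the z grid or sharpen the edges"
        )
    return DensityProfile(z, rho, spec.solvent_rho), spec


def gen_slab_density(
    d: float,
    contrast: float,
    z_grid: np.ndarray | None = None,
    solvent_rho: float = WATER_RHO,
) -> DensityProfile:
    """Top-hat contrast slab: rho = solvent + contrast on |z| <= d.

    The analytic oracle for the form factor of this profile is
    |F(q)| = |2 contrast sin(q d) / q|, with zeros at q = n pi / d.
    """
    if z_grid is None:
        z_grid = default_z_grid()
    z = np.asarray(z_grid, float)
    if d < 0:
        raise ValidationError("slab half-width d must be >= 0")
    if d > z[-1]:
        raise ValidationError("slab exceeds the z grid")
    rho = np.where(np.abs(z) <= d + 1e-12, solvent_rho + contrast, solvent_rho)
    # a grid point sitting exactly on the discontinuity carries the mean of
    # the two sides, so trapezoidal quadrature sees a symmetric edge and the
    # Fourier transform stays O((q dz)^2) accurate
    on_edge = np.isclose(np.abs(z), d, rtol=0.0, atol=1e-12)
    rho = np.where(on_edge, solvent_rho + 0.5 * contrast, rho)
    return DensityProfile(z, rho.astype(float), solvent_rho)


# per-carbon baseline |S_CH| magnitudes, loosely shaped like a POPC bilayer:
# a plateau over the upper chain and a decay toward the terminal methyl,
# with a dip at the oleate double bond (C9-C10).
def _baseline_palmitate() -> dict[int, float]:
    mags = {}
    for c in range(2, 17):
        if c <= 8:
            mags[c] = 0.21
        else:
            mags[c] = max(0.21 - 0.02 * (c - 8), 0.05)
    return mags


def _baseline_oleate() -> dict[int, float]:
    mags = {}
    for c in range(2, 19):
        if c in (9, 10):
            mags[c] = 0.05
        elif c <= 8:
            mags[c] = 0.18
        else:
            mags[c] = max(0.18 - 0.018 * (c - 10), 0.04)
    return mags


@dataclass
class OPModelSpec:
    """Cholesterol-ordering response model for synthetic order parameters.

    |S(c)| = |S0| * (1 + gain * min(c, saturation)) + noise, with c the
    cholesterol content in mol %.  The ordering gain of 0.02/mol % with
    saturation at 40 mol % roughly doubles the chain order over the
    studied range, mimicking the condensing response of a PC bilayer.
    """

    gain: float = 0.02  # per mol %
    saturation: float = 40.0  # mol %
    noise_sd: float = 0.0
    seed: int | None = None
    baseline: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "palmitate": _baseline_palmitate(),
            "oleate": _baseline_oleate(),
        }
    )


def gen_op_profiles(
    spec: OPModelSpec, concentrations: list[float]
) -> tuple[list[OrderParameterSet], OPModelSpec]:
    """Order-parameter sets (already hydrogen-averaged, signed negative)
    at the given cholesterol concentrations (mol %); returns (sets, truth).

    Oleate C2 is emitted forked with two values split +-20 % around its
    baseline, matching the structure of real hydrogen-averaged data.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for c in concentrations:
        if not 0.0 <= c <= 100.0:
            raise ValidationError("concentration must be in [0, 100] mol %")
        factor = 1.0 + spec.gain * min(c, spec.saturation)
        entries = []
        for chain, baseline in spec.baseline.items():
            for carbon, mag in baseline.items():
                if chain == "oleate" and carbon == 2:
                    for hyd, split in ((1, 1.2), (2, 0.8)):
                        s = -mag * split * factor + rng.normal(0.0, spec.noise_sd)
                        entries.append(
                            OPEntry(chain, carbon, hyd, _cap_s(s), forked=True)
                        )
                else:
                    s = -mag * factor + rng.normal(0.0, spec.noise_sd)
                    entries.append(OPEntry(chain, carbon, 1, _cap_s(s)))
        out.append(OrderParameterSet(c / 100.0, entries))
    return out, spec


def _cap_s(s: float) -> float:
    if abs(s) > 0.5:
        raise ValidationError(
            f"|S_CH| = {abs(s):.3f} exceeds the physical cap of 0.5; "
            "reduce gain, baseline or noise"
        )
    return float(s)


def gen_brownian_traj(
    d: float,
    n_particles: int,
    n_steps: int,
    dt: float,
    leaflet_drift: float = 0.0,
    seed: int | None = None,
) -> tuple[PlanarTrajectorySet, float]:
    """Planar Brownian trajectories with diffusion coefficient ``d``.

    ``d`` in um^2/s, ``dt`` in ns, drift in nm/ns (applied along +x to the
    upper leaflet and -x to the lower).  Steps are independent Gaussians
    with per-axis variance 2 D dt.  Returns (trajectories, ground-truth D).
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if d < 0:
        raise ValidationError("D must be >= 0")
    if n_particles < 2:
        raise ValidationError("need >= 2 particles (one per leaflet)")
    rng = np.random.default_rng(seed)
    d_nm2_ns = d * 1e-3  # 1 um^2/s = 1e-3 nm^2/ns
    sigma = np.sqrt(2.0 * d_nm2_ns * dt)
    steps = rng.standard_normal((n_particles, n_steps, 2)) * sigma
    pos = np.concatenate(
        [np.zeros((n_particles, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    times = np.arange(n_steps + 1) * dt
    half = n_particles // 2
    leaflet = np.array(["upper"] * half + ["lower"] * (n_particles - half))
    if leaflet_drift:
        drift = np.zeros((n_particles, 1, 2))
        drift[:half, 0, 0] = leaflet_drift
        drift[half:, 0, 0] = -leaflet_drift
        pos = pos + drift * times[None, :, None]
    return PlanarTrajectorySet(times, pos, leaflet), d


def gen_finite_size_series(
    d_inf: float,
    mu_m: float,
    geom: MembraneGeometry,
    L_list: list[float],
    rel_noise: float = 0.0,
    seed: int | None = None,
) -> tuple[FiniteSizeSeries, tuple[float, float]]:
    """Forward-modelled D_PBC(L) series; returns (series, (d_inf, mu_m)).

    D_PBC is evaluated with the periodic Saffman-Delbrueck model and
    perturbed multiplicatively by seeded Gaussian noise of relative size
    ``rel_noise``; the stated error of each point is rel_noise * D_PBC.
    The default box edges follow the simulated pure-POPC systems
    (4.4, 9.0 and 18.1 nm for the small/medium/large boxes).
    """
    rng = np.random.default_rng(seed)
    points = []
    for L in L_list:
        d_clean = dpbc_model(L, d_inf, mu_m, geom)
        if d_clean <= 0:
            raise ValidationError(
                f"model D_PBC <= 0 at L = {L} nm; box too small for these "
                "parameters"
            )
        noise = rng.normal(0.0, rel_noise) if rel_noise > 0 else 0.0
        d_noisy = d_clean * (1.0 + noise)
        points.append((float(L), float(d_noisy), float(rel_noise * d_noisy)))
    return FiniteSizeSeries(points, geom), (d_inf, mu_m)
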