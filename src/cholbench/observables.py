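"""Domain containers and file I/O for membrane observables.

All quantities are stored in one canonical unit system so that the
hydrodynamic formulas can mix thermal energies and viscosities without
silent unit bugs:

====================  =========
length                nm
wave vector           nm^-1
time / lag time       ns
diffusion             um^2/s
viscosity             mPa s
temperature           K
electron density      e/nm^3
====================  =========

Converters, where needed, live at the I/O boundary only.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ACYL_CHAINS",
    "CHAINS",
    "OPEntry",
    "OrderParameterSet",
    "DensityProfile",
    "FormFactorCurve",
    "MSDCurve",
    "MembraneGeometry",
    "FiniteSizeSeries",
    "PBCFitResult",
    "average_equivalent_hydrogens",
    "read_order_parameters",
    "read_density_profile",
    "write_density_profile",
    "read_form_factor",
    "write_form_factor",
    "read_msd_xvg",
    "write_msd_xvg",
    "load_study_config",
]

#: Acyl chains of POPC.  sn-1 is fully saturated palmitate (C2..C16),
#: sn-2 is mono-unsaturated oleate (C2..C18).
ACYL_CHAINS = ("palmitate", "oleate")
#: All recognised chain tags; headgroup and glycerol-backbone C-H bonds share
#: one tag and are excluded from acyl-chain quality metrics by default.
CHAINS = ACYL_CHAINS + ("headgroup-glycerol",)

_CARBON_RANGE = {"palmitate": (2, 16), "oleate": (2, 18)}


class ValidationError(ValueError):
    """Raised when an observable container violates its invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains NaN or Inf values")


@dataclass(frozen=True)
class OPEntry:
    """One C-H bond order parameter S_CH.

    ``forked`` marks the two inequivalent hydrogens of the oleate C2
    carbon, which lack rotational averaging and are kept separate.
    """

    chain: str
    carbon: int
    hydrogen: int
    s_ch: float
    err: float | None = None
    forked: bool = False

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValidationError(f"unknown chain {self.chain!r}")
        if not np.isfinite(self.s_ch):
            raise ValidationError("S_CH must be finite")
        if abs(self.s_ch) > 0.5:
            raise ValidationError(f"|S_CH| = {abs(self.s_ch):.3f} exceeds 0.5")
        if self.err is not None and (not np.isfinite(self.err) or self.err < 0):
            raise ValidationError("error must be finite and >= 0")
        lo_hi = _CARBON_RANGE.get(self.chain)
        if lo_hi is not None and not (lo_hi[0] <= self.carbon <= lo_hi[1]):
            raise ValidationError(
                f"{self.chain} carbon index {self.carbon} outside {lo_hi}"
            )


@dataclass
class OrderParameterSet:
    """S_CH values of one membrane at one cholesterol mole fraction.

    Parameters
    ----------
    chol_frac
        Cholesterol mole fraction in [0, 1].
    entries
        One :class:`OPEntry` per (chain, carbon, hydrogen).
    unsigned
        True when the source provides magnitudes only (e.g. unsigned
        13C NMR data); comparisons then use ``|S_CH|``.
    """

    chol_frac: float
    entries: list[OPEntry]
    unsigned: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.chol_frac <= 1.0:
            raise ValidationError("chol_frac must be within [0, 1]")
        seen: set[tuple[str, int, int]] = set()
        for e in self.entries:
            key = (e.chain, e.carbon, e.hydrogen)
            if key in seen:
                raise ValidationError(f"duplicate entry for {key}")
            seen.add(key)

    @property
    def chol_pct(self) -> float:
        """Cholesterol content in mol %."""
        return 100.0 * self.chol_frac

    def select(self, chain: str) -> list[OPEntry]:
        return [e for e in self.entries if e.chain == chain]

    def carbons(self, chain: str) -> list[int]:
        return sorted({e.carbon for e in self.select(chain)})

    def profile(self, chain: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-carbon profile (carbons, values) for an averaged set.

        Forked oleate-C2 hydrogens are averaged here (the deviation of
        each branch is handled upstream where needed); other carbons are
        expected to carry a single value.
        """
        carbons = self.carbons(chain)
        values = []
        for c in carbons:
            vals = [e.s_ch for e in self.select(chain) if e.carbon == c]
            values.append(float(np.mean(vals)))
        return np.asarray(carbons, float), np.asarray(values, float)


def average_equivalent_hydrogens(ops: OrderParameterSet) -> OrderParameterSet:
    """Average S_CH over the equivalent hydrogens of each acyl-chain carbon.

    CH2 (CH3) hydrogens rotate freely and are magnetically equivalent, so
    their order parameters are averaged to a single value per carbon; the
    uncertainty of the group is the mean of the member uncertainties (the
    hydrogens are not independent measurements, so no 1/sqrt(n) reduction).

    Two exceptions:

    * the oleate C2 hydrogens are forked (no rotational averaging in
      either simulation or experiment); the two values are kept, ordered
      by decreasing magnitude, and flagged ``forked``;
    * headgroup/glycerol entries pass through unchanged.

    The operation is idempotent.
    """
    out: list[OPEntry] = []
    for chain in CHAINS:
        members = ops.select(chain)
        if chain == "headgroup-glycerol":
            out.extend(members)
            continue
        for carbon in sorted({e.carbon for e in members}):
            group = [e for e in members if e.carbon == carbon]
            if chain == "oleate" and carbon == 2:
                if len(group) != 2:
                    raise ValidationError(
                        "oleate C2 must carry exactly 2 hydrogens "
                        f"(found {len(group)})"
                    )
                ordered = sorted(group, key=lambda e: abs(e.s_ch), reverse=True)
                out.extend(
                    replace(e, hydrogen=i + 1, forked=True)
                    for i, e in enumerate(ordered)
                )
                continue
            errs = [e.err for e in group]
            err = None if any(x is None for x in errs) else float(np.mean(errs))
            out.append(
                OPEntry(
                    chain=chain,
                    carbon=carbon,
                    hydrogen=1,
                    s_ch=float(np.mean([e.s_ch for e in group])),
                    err=err,
                )
            )
    return OrderParameterSet(ops.chol_frac, out, unsigned=ops.unsigned)


@dataclass
class DensityProfile:
    """Electron density rho(z) along the membrane normal.

    ``z`` is in nm, symmetric about the bilayer center at z = 0 and
    uniformly spaced; ``rho`` in e/nm^3.  ``solvent_rho`` is the bulk
    water electron density used as the contrast baseline.
    """

    z: np.ndarray
    rho: np.ndarray
    solvent_rho: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.rho = np.asarray(self.rho, float)
        if self.z.ndim != 1 or self.z.shape != self.rho.shape:
            raise ValidationError("z and rho must be 1D arrays of equal length")
        _check_finite(self.z, "z grid")
        _check_finite(self.rho, "density")
        if len(self.z) < 2 or np.any(np.diff(self.z) <= 0):
            raise ValidationError("z grid must be strictly increasing")
        dz = np.diff(self.z)
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=0):
            raise ValidationError("z grid spacing must be constant")
        if not np.isfinite(self.solvent_rho):
            raise ValidationError("solvent_rho must be finite")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass
class FormFactorCurve:
    """X-ray form factor magnitude |F(q)|, e/nm^2, on a q >= 0 grid (nm^-1)."""

    q: np.ndarray
    f_abs: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.f_abs = np.asarray(self.f_abs, float)
        if self.q.shape != self.f_abs.shape or self.q.ndim != 1:
            raise ValidationError("q and f_abs must be 1D arrays of equal length")
        _check_finite(self.q, "q grid")
        _check_finite(self.f_abs, "|F|")
        if np.any(self.q < 0):
            raise ValidationError("q must be >= 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q grid must be strictly increasing")
        if np.any(self.f_abs < -1e-12):
            raise ValidationError("|F| must be >= 0")


@dataclass
class MSDCurve:
    """Mean squared displacement vs lag time (ns, nm^2)."""

    lag: np.ndarray
    msd: np.ndarray

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, float)
        self.msd = np.asarray(self.msd, float)
        if self.lag.shape != self.msd.shape or self.lag.ndim != 1:
            raise ValidationError("lag and msd must be 1D arrays of equal length")
        _check_finite(self.lag, "lag")
        _check_finite(self.msd, "msd")
        if np.any(self.lag < 0) or np.any(np.diff(self.lag) <= 0):
            raise ValidationError("lag must be >= 0 and strictly increasing")
        if np.any(self.msd < -1e-12):
            raise ValidationError("msd must be >= 0")
        if self.lag[0] == 0 and abs(self.msd[0]) > 1e-12:
            raise ValidationError("msd must vanish at zero lag")


@dataclass
class MembraneGeometry:
    """Box and hydrodynamic geometry entering the finite-size correction.

    ``h`` is the hydrodynamic membrane thickness (taken equal to the
    electron-density peak-to-peak thickness), ``H = (L_z - h)/2`` half the
    water-layer thickness.  ``mu_f`` defaults to the CHARMM TIP3P water
    shear viscosity interpolated to 298 K.
    """

    L_z: float
    h: float
    T: float = 298.0
    mu_f: float = 0.3228
    L: float | None = None

    def __post_init__(self) -> None:
        for name in ("L_z", "h", "T", "mu_f"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite")
        if self.L is not None and not (np.isfinite(self.L) and self.L > 0):
            raise ValidationError("L must be positive and finite")
        if self.L_z <= self.h:
            raise ValidationError("L_z must exceed the membrane thickness h")

    @property
    def H(self) -> float:
        """Half water-layer thickness, (L_z - h)/2, nm."""
        return 0.5 * (self.L_z - self.h)


@dataclass
class FiniteSizeSeries:
    """D_PBC measured at several box edge lengths L, with shared geometry.

    ``points`` is a list of ``(L_nm, d_pbc_um2_per_s, d_err_or_None)``;
    ``geom`` carries h, H, T and mu_f averaged over the system sizes.
    """

    points: list[tuple[float, float, float | None]]
    geom: MembraneGeometry

    def __post_init__(self) -> None:
        if len({round(p[0], 12) for p in self.points}) < 2:
            raise ValidationError("need >= 2 distinct box sizes L for fitting")
        for L, d, derr in self.points:
            if not (np.isfinite(L) and L > 0):
                raise ValidationError("L must be positive")
            if not (np.isfinite(d) and d > 0):
                raise ValidationError("d_pbc must be positive")
            if derr is not None and (not np.isfinite(derr) or derr < 0):
                raise ValidationError("d_err must be >= 0")

    @property
    def L(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], float)

    @property
    def d_pbc(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], float)

    @property
    def d_err(self) -> np.ndarray | None:
        errs = [p[2] for p in self.points]
        if any(e is None for e in errs):
            return None
        return np.array(errs, float)


@dataclass
class PBCFitResult:
    """Finite-size-corrected diffusion and membrane viscosity.

    ``l_sd`` is the Saffman-Delbrueck length mu_m*h/(2*mu_f).  The raw
    Monte-Carlo viscosity samples are kept because their distribution is
    often skewed and a Gaussian summary would mislead.
    """

    d_inf: float
    mu_m: float
    l_sd: float
    d_inf_err: float | None = None
    mu_m_samples: np.ndarray | None = None
    d_inf_samples: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.degenerate:
            return
        if not (self.d_inf > 0 and self.mu_m > 0):
            raise ValidationError("d_inf and mu_m must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Path, comment: tuple[str, ...]) -> Iterable[tuple[int, str]]:
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(comment):
            continue
        yield i, line


def read_order_parameters(
    path: str | Path,
    chol_frac: float,
    dialect: str = "auto",
    unsigned: bool = False,
) -> OrderParameterSet:
    """Read an order-parameter table.

    Two dialects are supported: ``whitespace`` (NMRlipids-style rows
    ``chain carbon hydrogen value [error]``, ``#`` comments) and ``csv``
    (header ``chain,carbon,hydrogen,value,error``).  ``auto`` picks CSV
    when the first data line contains a comma.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if dialect == "auto":
        first = next(
            (l for l in text.splitlines() if l.strip() and not l.startswith("#")), ""
        )
        dialect = "csv" if "," in first else "whitespace"

    entries: list[OPEntry] = []

    def _entry(lineno: int, fields: Sequence[str]) -> OPEntry:
        if len(fields) not in (4, 5):
            raise ParseError(
                f"{path}:{lineno}: expected 4 or 5 fields, got {len(fields)}"
            )
        try:
            return OPEntry(
                chain=fields[0],
                carbon=int(fields[1]),
                hydrogen=int(fields[2]),
                s_ch=float(fields[3]),
                err=float(fields[4]) if len(fields) == 5 and fields[4] != "" else None,
            )
        except ValidationError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed row ({exc})") from exc

    if dialect == "csv":
        reader = csv.reader(text.splitlines())
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "chain":
                continue
            entries.append(_entry(lineno, [f.strip() for f in row]))
    elif dialect == "whitespace":
        for lineno, line in _data_lines(path, ("#",)):
            entries.append(_entry(lineno, line.split()))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not entries:
        warnings.warn(f"{path}: no order-parameter rows found", stacklevel=2)
    return OrderParameterSet(chol_frac, entries, unsigned=unsigned)


def _read_two_column(path: Path, comment: tuple[str, ...], sep: str | None):
    xs, ys = [], []
    for lineno, line in _data_lines(path, comment):
        parts = line.split(sep) if sep else line.split()
        parts = [p for p in (s.strip() for s in parts) if p]
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric data") from None
    return np.asarray(xs), np.asarray(ys)


def read_density_profile(path: str | Path, solvent_rho: float | None = None) -> DensityProfile:
    """Read a 2-column CSV ``z_nm,rho_e_nm3`` electron density profile.

    ``solvent_rho`` defaults to the mean density of the outermost 5 % of
    grid points on each side (the water plateau).
    """
    path = Path(path)
    z, rho = _read_two_column(path, ("#",), ",")
    if solvent_rho is None:
        k = max(1, len(z) // 20)
        solvent_rho = float(np.mean(np.concatenate([rho[:k], rho[-k:]])))
    return DensityProfile(z, rho, solvent_rho)


def write_density_profile(profile: DensityProfile, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# z_nm,rho_e_nm3\n")
        fh.write(f"# solvent_rho={profile.solvent_rho!r}\n")
        for z, r in zip(profile.z, profile.rho):
            fh.write(f"{float(z)!r},{float(r)!r}\n")


def read_form_factor(path: str | Path) -> FormFactorCurve:
    """Read a 2-column CSV ``q_invnm,absF``."""
    q, f = _read_two_column(Path(path), ("#",), ",")
    return FormFactorCurve(q, f)


def write_form_factor(ff: FormFactorCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# q_invnm,absF\n")
        for q, f in zip(ff.q, ff.f_abs):
            fh.write(f"{float(q)!r},{float(f)!r}\n")


def read_msd_xvg(path: str | Path) -> MSDCurve:
    """Read an xvg-style MSD file (two numeric columns; ``#``/``@`` lines skipped)."""
    lag, msd = _read_two_column(Path(path), ("#", "@"), None)
    return MSDCurve(lag, msd)


def write_msd_xvg(msd: MSDCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("@ title \"Mean squared displacement\"\n")
        fh.write("@ xaxis label \"lag (ns)\"\n")
        fh.write("@ yaxis label \"MSD (nm^2)\"\n")
        for t, m in zip(msd.lag, msd.msd):
            fh.write(f"{float(t)!r} {float(m)!r}\n")


def load_study_config(path: str | Path) -> dict:
    """Load a YAML study config naming dataset files.

    Expected layout::

        datasets:
          - source: sim            # sim | exp
            observable: order_parameters
            chol_pct: 20
            path: data/sim_op_20.dat

    Returns the parsed mapping; path resolution is left to the caller.
    """
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "datasets" not in cfg:
        raise ParseError(f"{path}: config must contain a 'datasets' list")
    for ds in cfg["datasets"]:
        for key in ("source", "observable", "chol_pct", "path"):
            if key not in ds:
                raise ParseError(f"{path}: dataset entry missing key {key!r}")
        if ds["source"] not in ("sim", "exp"):
            raise ParseError(f"{path}: source must be 'sim' or 'exp'")
    return cfg
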