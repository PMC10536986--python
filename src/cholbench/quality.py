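"""Assembly of per-observable relative deviations into a cumulative
force-field quality profile.

Each component - palmitate and oleate order parameters, the first two
form-factor minima, and the finite-size-corrected diffusion coefficient -
contributes a nonnegative relative deviation (%) versus cholesterol
content; stacked, they give one cumulative measure of how far a force
field sits from experiment across the concentration range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interpolate import Curve1D, Surface2D, relative_deviation_curve
from .observables import ValidationError

__all__ = [
    "COMPONENT_ORDER",
    "QualityProfile",
    "op_quality",
    "formfactor_quality",
    "diffusion_quality",
    "cumulative_quality",
    "write_quality_report",
    "plot_cumulative_quality",
]

#: Fixed stacking order for reproducible reports and figures.  The
#: electron-density component is computable but off by default.
COMPONENT_ORDER = (
    "formfactor_min1",
    "formfactor_min2",
    "palmitate_op",
    "oleate_op",
    "diffusion",
    "density",
)


@dataclass
class QualityProfile:
    """Relative deviation (%) of one observable vs cholesterol mol %."""

    component: str
    curve: Curve1D

    def __post_init__(self) -> None:
        if self.component not in COMPONENT_ORDER:
            raise ValidationError(
                f"unknown component {self.component!r}; expected one of "
                f"{COMPONENT_ORDER}"
            )
        if np.any(self.curve.values < 0):
            raise ValidationError("relative deviations must be >= 0")


def op_quality(sim: Surface2D, exp: Surface2D, chain: str) -> QualityProfile:
    """Order-parameter quality of one acyl chain.

    The deviation surface is averaged over the carbon axis and normalized
    by the equally averaged |exp| order parameters at each concentration.
    """
    if chain not in ("palmitate", "oleate"):
        raise ValidationError("chain must be 'palmitate' or 'oleate'")
    return QualityProfile(f"{chain}_op", relative_deviation_curve(sim, exp))


def formfactor_quality(
    sim_minima: tuple[Curve1D, Curve1D],
    exp_minima: tuple[Curve1D, Curve1D],
) -> tuple[QualityProfile, QualityProfile, Curve1D]:
    """Quality from the positions of the first two form-factor minima.

    Each minimum track contributes |q_sim - q_exp| / q_exp * 100; the two
    profiles are returned individually together with their summed curve.
    """
    profiles = []
    for i, (sim, exp) in enumerate(zip(sim_minima, exp_minima), start=1):
        profiles.append(
            QualityProfile(f"formfactor_min{i}", relative_deviation_curve(sim, exp))
        )
    total = Curve1D(
        profiles[0].curve.chol_grid.copy(),
        profiles[0].curve.values + profiles[1].curve.values,
    )
    return profiles[0], profiles[1], total


def diffusion_quality(sim_d: Curve1D, exp_d: Curve1D) -> QualityProfile:
    """Quality of the finite-size-corrected lateral diffusion coefficient.

    Only PBC-corrected D_inf curves are meaningful here: the finite-size
    correction changes not just the magnitude but the cholesterol trend
    of the diffusion coefficient.
    """
    return QualityProfile("diffusion", relative_deviation_curve(sim_d, exp_d))


def cumulative_quality(profiles: list[QualityProfile]) -> pd.DataFrame:
    """Stack component deviations into a cumulative table.

    Returns a DataFrame indexed by cholesterol mol % with one column per
    component (in the fixed stack order) and a ``total`` column equal to
    their sum at every concentration.
    """
    if not profiles:
        raise ValidationError("need at least one quality profile")
    grid = profiles[0].curve.chol_grid
    for p in profiles[1:]:
        if not p.curve.same_grid(profiles[0].curve):
            raise ValidationError(
                f"component {p.component!r} is on a different cholesterol grid"
            )
    seen = [p.component for p in profiles]
    if len(set(seen)) != len(seen):
        raise ValidationError(f"duplicate components in {seen}")
    ordered = sorted(profiles, key=lambda p: COMPONENT_ORDER.index(p.component))
    df = pd.DataFrame(
        {p.component: p.curve.values for p in ordered},
        index=pd.Index(grid, name="chol_pct"),
    )
    df["total"] = df.sum(axis=1)
    return df


def write_quality_report(report: pd.DataFrame, path) -> None:
    """Write the cumulative quality table as CSV."""
    report.to_csv(path, float_format="%.10g")


def plot_cumulative_quality(report: pd.DataFrame, path, title: str = "") -> None:
    """Stacked-area rendering of the cumulative quality report."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    components = [c for c in report.columns if c != "total"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.stackplot(
        report.index.to_numpy(),
        [report[c].to_numpy() for c in components],
        labels=components,
    )
    ax.set_xlabel("cholesterol (mol %)")
    ax.set_ylabel("relative deviation (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
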