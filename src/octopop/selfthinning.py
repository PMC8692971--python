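"""Self-thinning lines and log-log biomass-density trajectories.

Crowded, undisturbed populations of sessile organisms settle onto a
log-log equilibrium between mean individual biomass and density whose
theoretical slope is -3/2: further biomass growth requires density
decay.  Disturbed populations fall below the line; their multi-year
(log10 density, log10 mean colony biomass) path relative to the line
separates mortality-driven displacement from recovery.

The y-axis is MEAN LIVE BIOMASS PER COLONY (g), not biomass per unit
area — the -3/2 slope applies to individual mass.  A per-area y-axis
(which rotates the theoretical slope to -1/2) is available via
``per_area=True`` on :func:`fit_selfthinning_line`; everything is
log10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomassDensityPoint",
    "SelfThinningLine",
    "TrajectoryStep",
    "Trajectory",
    "fit_selfthinning_line",
    "theoretical_line",
    "trajectory",
    "trajectory_table",
]


@dataclass(frozen=True)
class BiomassDensityPoint:
    """One population-year in (density, mean colony biomass) space."""

    population_id: str
    year: int
    density_per_m2: float
    mean_colony_biomass_g: float

    def __post_init__(self) -> None:
        if not self.density_per_m2 > 0:
            raise ValueError(
                f"{self.population_id} ({self.year}): density must be > 0 "
                f"(log-transformable), got {self.density_per_m2}"
            )
        if not self.mean_colony_biomass_g > 0:
            raise ValueError(
                f"{self.population_id} ({self.year}): mean colony biomass must be "
                f"> 0 (log-transformable), got {self.mean_colony_biomass_g}"
            )

    @property
    def log10_density(self) -> float:
        return math.log10(self.density_per_m2)

    @property
    def log10_biomass(self) -> float:
        return math.log10(self.mean_colony_biomass_g)


@dataclass(frozen=True)
class SelfThinningLine:
    """Fitted (or theoretical) log10-log10 line with diagnostics."""

    slope: float
    intercept: float
    r_squared: float | None
    n_points: int
    p_value: float | None = None
    residual_se: float | None = None

    def predict_log10_biomass(self, log10_density: float) -> float:
        return self.intercept + self.slope * log10_density

    def residual(self, point: BiomassDensityPoint) -> float:
        """Signed vertical offset of a point from the line (log10 units)."""
        return point.log10_biomass - self.predict_log10_biomass(point.log10_density)


def fit_selfthinning_line(
    points: Sequence[BiomassDensityPoint],
    method: Literal["ols", "major_axis"] = "ols",
    per_area: bool = False,
) -> SelfThinningLine:
    """Least-squares line through log10(biomass) vs log10(density).

    Parameters
    ----------
    points
        At least two strictly positive (density, biomass) pairs.
    method
        ``"ols"`` regresses log biomass on log density.  ``"major_axis"``
        uses the standardized major axis (slope sign from the
        correlation, magnitude sd(y)/sd(x)) for when both axes carry
        comparable error; diagnostics other than slope/intercept are
        reported from the OLS fit.
    per_area
        If true, the y-variable becomes per-area biomass
        (mean colony biomass x density); the theoretical slope in that
        frame is -1/2 rather than -3/2.
    """
    if len(points) < 2:
        raise ValueError(f"need at least 2 points to fit a line, got {len(points)}")
    x = np.array([p.log10_density for p in points])
    y = np.array([p.log10_biomass for p in points])
    if per_area:
        y = y + x
    if np.ptp(x) == 0:
        raise ValueError("all densities identical: slope is undefined")

    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r_squared: float | None = float(res.rvalue) ** 2
    p_value: float | None = float(res.pvalue)

    if method == "major_axis":
        sign = math.copysign(1.0, float(res.rvalue)) if res.rvalue != 0 else 1.0
        slope = sign * float(np.std(y, ddof=1) / np.std(x, ddof=1))
        intercept = float(y.mean() - slope * x.mean())
    elif method != "ols":
        raise ValueError(f"method must be 'ols' or 'major_axis', got {method!r}")

    n = len(points)
    if n < 3:
        warnings.warn(
            "fit through 2 points is exact interpolation; R^2 and p are "
            "uninformative",
            stacklevel=2,
        )
        r_squared, p_value, residual_se = 1.0, None, None
    else:
        resid = y - (intercept + slope * x)
        residual_se = float(np.sqrt((resid**2).sum() / (n - 2)))
    if slope >= 0:
        warnings.warn(
            f"fitted slope {slope:.3g} is non-negative; points do not look "
            "like a self-thinning population set",
            stacklevel=2,
        )
    return SelfThinningLine(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_points=n,
        p_value=p_value,
        residual_se=residual_se,
    )


def theoretical_line(
    anchor_density_per_m2: float,
    anchor_mean_biomass_g: float,
    slope: float = -1.5,
) -> SelfThinningLine:
    """The -3/2 (by default) line through a given anchor point."""
    if not (anchor_density_per_m2 > 0 and anchor_mean_biomass_g > 0):
        raise ValueError("anchor point must be strictly positive")
    intercept = math.log10(anchor_mean_biomass_g) - slope * math.log10(
        anchor_density_per_m2
    )
    return SelfThinningLine(
        slope=slope, intercept=intercept, r_squared=None, n_points=0, p_value=None
    )


@dataclass(frozen=True)
class TrajectoryStep:
    """One population-year placed relative to the self-thinning line."""

    year: int
    log10_density: float
    log10_biomass: float
    residual: float
    on_line: bool
    # displacement from the previous census, None for the first point
    d_log10_density: float | None
    d_log10_biomass: float | None


@dataclass(frozen=True)
class Trajectory:
    population_id: str
    steps: tuple[TrajectoryStep, ...]
    classification: str  # on-line | toward-line | away-from-line | along-line
    tolerance: float


def trajectory(
    series: Sequence[BiomassDensityPoint],
    line: SelfThinningLine,
    tolerance: float | None = None,
) -> Trajectory:
    """Map a population's yearly points against a self-thinning line.

    ``tolerance`` is the |residual| band treated as "on the line";
    it defaults to the line's residual standard error (or 0.05 log10
    units when the line carries no fit diagnostics).  The net movement is
    classified by comparing the change in |residual| between the first
    and last census against the tolerance: growth along the equilibrium
    keeps |residual| roughly constant, disturbance increases it, and
    recovery shrinks it.
    """
    if not series:
        raise ValueError("trajectory needs at least one point")
    years = [p.year for p in series]
    if len(set(years)) != len(years):
        dup = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate census years in series: {dup}")
    if years != sorted(years):
        raise ValueError("series must be sorted by year")
    pops = {p.population_id for p in series}
    if len(pops) > 1:
        raise ValueError(f"series mixes populations: {sorted(pops)}")

    if tolerance is None:
        tolerance = line.residual_se if line.residual_se is not None else 0.05

    steps: list[TrajectoryStep] = []
    prev: BiomassDensityPoint | None = None
    for p in series:
        r = line.residual(p)
        steps.append(
            TrajectoryStep(
                year=p.year,
                log10_density=p.log10_density,
                log10_biomass=p.log10_biomass,
                residual=r,
                on_line=abs(r) <= tolerance,
                d_log10_density=None if prev is None else p.log10_density - prev.log10_density,
                d_log10_biomass=None if prev is None else p.log10_biomass - prev.log10_biomass,
            )
        )
        prev = p

    first, last = steps[0], steps[-1]
    if last.on_line and first.on_line:
        classification = "on-line"
    else:
        delta = abs(last.residual) - abs(first.residual)
        if delta > tolerance:
            classification = "away-from-line"
        elif delta < -tolerance:
            classification = "toward-line"
        else:
            classification = "along-line"
    return Trajectory(
        population_id=series[0].population_id,
        steps=tuple(steps),
        classification=classification,
        tolerance=tolerance,
    )


def trajectory_table(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-form CSV-ready table of trajectory steps."""
    rows = []
    for t in trajectories:
        for s in t.steps:
            rows.append(
                dict(
                    population=t.population_id,
                    year=s.year,
                    log10_density=s.log10_density,
                    log10_mean_biomass=s.log10_biomass,
                    residual=s.residual,
                    on_line=s.on_line,
                    classification=t.classification,
                )
            )
    return pd.DataFrame(rows)
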