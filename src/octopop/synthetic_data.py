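"""Synthetic survey and temperature generators with known ground truth.

Everything here is a pure function of (parameters, seed).  Population
generators split the scenario seed per quadrat index, so adding a
quadrat to a scenario never reshuffles the draws of existing quadrats.
Temperature simulation returns, alongside the series, a ledger of every
injected anomaly day so detection can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .selfthinning import SelfThinningLine
from .survey_data import (
    STATUS_ALIVE,
    STATUS_STANDING_DEAD,
    ColonyRecord,
    PopulationSurvey,
    QuadratSurvey,
    SpeciesConfig,
    builtin_species_config,
)

__all__ = [
    "PopulationScenario",
    "DisturbanceEvent",
    "DynamicsParams",
    "simulate_population",
    "apply_disturbance",
    "step_dynamics",
    "simulate_temperature",
]

_TOL = 1e-9


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Stable sub-stream: same (seed, key) always yields the same stream."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class PopulationScenario:
    """Parameters of an undisturbed synthetic population."""

    species: str
    n_quadrats: int
    quadrat_area_m2: float
    initial_density_per_m2: float
    height_mean_log_cm: float = math.log(12.0)
    height_sd_log: float = 0.45
    on_line: SelfThinningLine | None = None
    population_id: str = "synthetic"
    year: int = 2003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_quadrats < 1:
            raise ValueError("n_quadrats must be >= 1")
        if not self.quadrat_area_m2 > 0:
            raise ValueError("quadrat_area_m2 must be > 0")
        if not self.initial_density_per_m2 > 0:
            raise ValueError("initial_density_per_m2 must be > 0")
        if not (
            math.isfinite(self.height_mean_log_cm) and math.isfinite(self.height_sd_log)
        ):
            raise ValueError("height distribution parameters must be finite")


@dataclass(frozen=True)
class DisturbanceEvent:
    """An acute mortality event of tunable severity and size-dependence.

    ``affected_prob_by_size`` gives, per size class of the species
    config, the probability that a surviving colony is partially
    injured; a scalar applies to all classes.  Partial recent-injury
    extent among affected colonies is Beta-distributed.
    """

    year: int
    total_mortality_prob: float
    injury_beta_a: float = 2.0
    injury_beta_b: float = 2.0
    affected_prob_by_size: float | Sequence[float] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            [self.total_mortality_prob]
            + list(np.atleast_1d(self.affected_prob_by_size).astype(float))
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must be in [0, 1]")

    def affected_prob(self, size_class_index: int, n_classes: int) -> float:
        probs = np.atleast_1d(self.affected_prob_by_size).astype(float)
        if probs.size == 1:
            return float(probs[0])
        if probs.size != n_classes:
            raise ValueError(
                f"affected_prob_by_size has {probs.size} entries for "
                f"{n_classes} size classes"
            )
        return float(probs[size_class_index])


@dataclass(frozen=True)
class DynamicsParams:
    """Annual post-disturbance dynamics: growth, epibiosis, delayed loss."""

    annual_growth_cm: float = 0.8  # slow-growing octocorals: < 3 cm/yr
    recruitment_rate: float = 0.0  # recruits per m2 per year
    delayed_mortality_prob: float = 0.0
    epibiosis_conversion_rate: float = 0.0  # recent -> old injury per year
    injury_threshold_pct: float = 10.0
    recruit_height_cm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "annual_growth_cm",
            "recruitment_rate",
            "delayed_mortality_prob",
            "epibiosis_conversion_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("delayed_mortality_prob", "epibiosis_conversion_rate"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")


def _size_class_index(height_cm: float, config: SpeciesConfig) -> int:
    edges = list(config.size_bins_cm[1:]) + [math.inf]
    return next(i for i, e in enumerate(edges) if height_cm <= e)


def simulate_population(
    scenario: PopulationScenario, config: SpeciesConfig | None = None
) -> PopulationSurvey:
    """Generate an uninjured population.

    Colony counts per quadrat are Poisson(density x area); heights are
    i.i.d. log-normal.  With ``on_line`` set, all heights are rescaled by
    a common factor so that the population's mean colony biomass sits
    exactly on the given self-thinning line at the realized density.
    """
    config = config or builtin_species_config(scenario.species)
    quadrats = []
    for qi in range(scenario.n_quadrats):
        rng = _rng(scenario.seed, 0, qi)
        n = int(rng.poisson(scenario.initial_density_per_m2 * scenario.quadrat_area_m2))
        heights = np.exp(
            rng.normal(scenario.height_mean_log_cm, scenario.height_sd_log, size=n)
        )
        quadrats.append(
            QuadratSurvey(
                quadrat_id=f"q{qi:02d}",
                area_m2=scenario.quadrat_area_m2,
                colonies=tuple(
                    ColonyRecord(
                        colony_id=f"q{qi:02d}-c{ci:03d}",
                        height_cm=float(h),
                        injury_recent_pct=0.0,
                        injury_old_pct=0.0,
                        status=STATUS_ALIVE,
                    )
                    for ci, h in enumerate(heights)
                ),
            )
        )
    survey = PopulationSurvey(
        population_id=scenario.population_id,
        species=scenario.species,
        year=scenario.year,
        quadrats=tuple(quadrats),
    )

    if scenario.on_line is not None:
        heights = np.array([c.height_cm for c in survey.colonies])
        if heights.size == 0:
            return survey
        realized_density = float(
            np.mean([q.n_alive / q.area_m2 for q in survey.quadrats])
        )
        if realized_density <= 0:
            return survey
        target_mean_b = 10.0 ** scenario.on_line.predict_log10_biomass(
            math.log10(realized_density)
        )
        current_mean_b = float(
            np.mean(config.allometric_a * heights**config.allometric_b)
        )
        scale = (target_mean_b / current_mean_b) ** (1.0 / config.allometric_b)
        quadrats = [
            replace(
                q,
                colonies=tuple(
                    replace(c, height_cm=c.height_cm * scale) for c in q.colonies
                ),
            )
            for q in survey.quadrats
        ]
        survey = survey.with_quadrats(quadrats)
    return survey


def _kill(c: ColonyRecord) -> ColonyRecord:
    return replace(
        c,
        injury_recent_pct=100.0 - c.injury_old_pct,
        status=STATUS_STANDING_DEAD,
    )


def apply_disturbance(
    survey: PopulationSurvey,
    event: DisturbanceEvent,
    config: SpeciesConfig | None = None,
) -> PopulationSurvey:
    """Impose an acute mortality event on every living colony.

    Each living colony dies outright with ``total_mortality_prob``
    (injury completes to 100%, status standing dead); otherwise it is
    partially injured with the size-class probability, drawing its new
    recent-injury extent from the Beta distribution, added on top of any
    existing injury and capped at 100%.
    """
    config = config or builtin_species_config(survey.species)
    n_classes = len(config.size_class_labels)
    quadrats = []
    for qi, q in enumerate(survey.quadrats):
        rng = _rng(event.seed, 1, qi)
        colonies = []
        for c in q.colonies:
            if c.status == STATUS_STANDING_DEAD:
                colonies.append(c)
                continue
            if rng.random() < event.total_mortality_prob:
                colonies.append(_kill(c))
                continue
            p_aff = event.affected_prob(_size_class_index(c.height_cm, config), n_classes)
            if rng.random() < p_aff:
                frac = rng.beta(event.injury_beta_a, event.injury_beta_b)
                new_recent = min(
                    c.injury_recent_pct + 100.0 * frac,
                    100.0 - c.injury_old_pct,
                )
                total = new_recent + c.injury_old_pct
                colonies.append(
                    replace(
                        c,
                        injury_recent_pct=new_recent,
                        status=(
                            STATUS_STANDING_DEAD
                            if abs(total - 100.0) <= _TOL
                            else STATUS_ALIVE
                        ),
                    )
                )
            else:
                colonies.append(c)
        quadrats.append(replace(q, colonies=tuple(colonies)))
    return replace(survey.with_quadrats(quadrats), year=event.year)


def step_dynamics(
    survey: PopulationSurvey, params: DynamicsParams, years: int
) -> list[PopulationSurvey]:
    """Run annual dynamics forward, returning one survey per year.

    Each year, in order: living colonies grow in height; recent injury
    converts to old injury (epibiosis); living colonies whose total
    injury exceeds the threshold die with ``delayed_mortality_prob``;
    new recruits of minimal size arrive as Poisson(rate x area) per
    quadrat.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    out: list[PopulationSurvey] = []
    current = survey
    for step in range(1, years + 1):
        quadrats = []
        for qi, q in enumerate(current.quadrats):
            rng = _rng(params.seed, 2, qi, step)
            colonies = []
            for c in q.colonies:
                if c.status == STATUS_STANDING_DEAD:
                    colonies.append(c)
                    continue
                h = c.height_cm + params.annual_growth_cm
                conv = c.injury_recent_pct * params.epibiosis_conversion_rate
                recent = c.injury_recent_pct - conv
                old = c.injury_old_pct + conv
                c = replace(c, height_cm=h, injury_recent_pct=recent, injury_old_pct=old)
                if (
                    c.injury_total_pct > params.injury_threshold_pct
                    and rng.random() < params.delayed_mortality_prob
                ):
                    c = _kill(c)
                colonies.append(c)
            n_rec = int(rng.poisson(params.recruitment_rate * q.area_m2))
            for ri in range(n_rec):
                colonies.append(
                    ColonyRecord(
                        colony_id=f"{q.quadrat_id}-r{step}{ri:02d}",
                        height_cm=params.recruit_height_cm,
                        injury_recent_pct=0.0,
                        injury_old_pct=0.0,
                        status=STATUS_ALIVE,
                    )
                )
            quadrats.append(replace(q, colonies=tuple(colonies)))
        current = replace(
            current.with_quadrats(quadrats), year=current.year + 1
        )
        out.append(current)
    return out


def simulate_temperature(
    first_year: int,
    last_year: int,
    seasonal_mean_c: float = 18.0,
    seasonal_amplitude_c: float = 5.0,
    ar1_phi: float = 0.0,
    noise_sd_c: float = 0.0,
    anomalies: Sequence[tuple[str, int, float]] = (),
    peak_doy: int = 227,
    seed: int = 0,
):
    """Daily temperature with seasonal cycle, AR(1) noise and anomalies.

    ``anomalies`` is a list of (start_date ISO string, length_days,
    magnitude_degC) boxcars added to the series; overlaps are an error.
    Returns ``(DailyTemperatureSeries, ledger)`` where the ledger is a
    DataFrame with one row per injected anomaly day (date, anomaly_c).
    The AR(1) noise has stationary marginal sd ``noise_sd_c``.

    Imports :mod:`octopop.thermal` lazily to avoid a hard module cycle.
    """
    from .thermal import DailyTemperatureSeries

    if not abs(ar1_phi) < 1:
        raise ValueError("|ar1_phi| must be < 1 for stationarity")
    dates = pd.date_range(f"{first_year}-01-01", f"{last_year}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    temps = seasonal_mean_c + seasonal_amplitude_c * np.cos(
        2 * math.pi * (doy - peak_doy) / 365.25
    )

    if noise_sd_c > 0:
        rng = _rng(seed, 3)
        # initial state drawn first so that extending the simulated span
        # reuses an identical noise prefix for the earlier years
        innov_sd = noise_sd_c * math.sqrt(1 - ar1_phi**2)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, noise_sd_c)
        eps = rng.normal(0.0, innov_sd, size=n)
        for t in range(1, n):
            noise[t] = ar1_phi * noise[t - 1] + eps[t]
        temps = temps + noise

    ledger_rows = []
    injected = np.zeros(n, dtype=bool)
    for start, length, magnitude in anomalies:
        if length < 1:
            raise ValueError(f"anomaly length must be >= 1, got {length}")
        t0 = pd.Timestamp(start)
        i0 = (t0 - dates[0]).days
        if i0 < 0 or i0 + length > n:
            raise ValueError(f"anomaly {start} (+{length} d) outside simulated span")
        sl = slice(i0, i0 + length)
        if injected[sl].any():
            raise ValueError(f"anomaly starting {start} overlaps a previous one")
        injected[sl] = True
        temps[sl] += magnitude
        for k in range(length):
            ledger_rows.append(
                dict(date=dates[i0 + k], anomaly_c=float(magnitude))
            )

    ledger = pd.DataFrame(ledger_rows, columns=["date", "anomaly_c"])
    return DailyTemperatureSeries(dates, temps), ledger
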