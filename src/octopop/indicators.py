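"""Population-level demographic indicators and baseline reconstruction.

Five indicators are computed per population and census: percentage of
affected colonies, mean extent of injury, density of living colonies,
live standing biomass, and colony size structure.  Biomass uses the
species allometric power law corrected multiplicatively for the injured
surface fraction.  The pre-disturbance baseline is reconstructed by
treating old injuries as pre-existing and recent injuries as healthy
tissue before the event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .survey_data import (
    STATUS_ALIVE,
    STATUS_STANDING_DEAD,
    ColonyRecord,
    PopulationSurvey,
    QuadratSurvey,
    SpeciesConfig,
)

__all__ = [
    "EmptyPopulationError",
    "IndicatorSet",
    "colony_biomass",
    "pct_affected",
    "mean_injury",
    "density",
    "population_biomass",
    "size_structure",
    "reconstruct_baseline",
    "compare_size_structures",
    "compute_indicators",
    "indicators_table",
]

_TOL = 1e-9


class EmptyPopulationError(ValueError):
    """An indicator was requested on a population with no eligible colonies."""


@dataclass(frozen=True)
class IndicatorSet:
    """The five population parameters for one (population, year)."""

    population_id: str
    year: int
    pct_affected: float
    mean_injury_pct: float
    mean_injury_se: float | None
    density_per_m2: float
    density_se: float | None
    biomass_g_per_m2: float
    biomass_se: float | None
    size_structure: dict[str, int]
    n_colonies: int


def colony_biomass(
    height_cm: float, injury_total_pct: float, config: SpeciesConfig
) -> float:
    """Live biomass (g) of one colony.

    Allometric biomass ``a * H**b`` scaled by the live surface fraction
    ``1 - injury/100``.  Strictly increasing in height and strictly
    decreasing in injury.
    """
    if not height_cm > 0:
        raise ValueError(f"height_cm must be > 0, got {height_cm}")
    if not (0 <= injury_total_pct <= 100):
        raise ValueError(
            f"injury_total_pct must be in [0, 100], got {injury_total_pct}"
        )
    allometric = config.allometric_a * height_cm ** config.allometric_b
    return allometric * (1.0 - injury_total_pct / 100.0)


def _colony_live_biomass(c: ColonyRecord, config: SpeciesConfig) -> float:
    return colony_biomass(c.height_cm, c.injury_total_pct, config)


def _injury_of_kind(c: ColonyRecord, kind: str) -> float:
    if kind == "any":
        return c.injury_total_pct
    if kind == "recent":
        return c.injury_recent_pct
    if kind == "old":
        return c.injury_old_pct
    raise ValueError(f"injury kind must be 'any', 'recent' or 'old', got {kind!r}")


def pct_affected(
    survey: PopulationSurvey, config: SpeciesConfig, injury_kind: str = "any"
) -> float:
    """Percentage of colonies with the selected injury strictly above the
    affected threshold (default 10%)."""
    colonies = survey.colonies
    if not colonies:
        raise EmptyPopulationError(
            f"population {survey.population_id} ({survey.year}) has no colonies"
        )
    thr = config.affected_threshold_pct
    n_affected = sum(1 for c in colonies if _injury_of_kind(c, injury_kind) > thr)
    return 100.0 * n_affected / len(colonies)


def _mean_se(values: Sequence[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def mean_injury(
    survey: PopulationSurvey, include_standing_dead: bool = True
) -> tuple[float, float | None]:
    """Mean total injured surface per colony, with its standard error.

    Standing-dead colonies count as 100% injured by default (cumulative
    reading of injury); set ``include_standing_dead=False`` to average
    over living colonies only.  Standard error is ``None`` for a single
    colony.
    """
    colonies = [
        c
        for c in survey.colonies
        if include_standing_dead or c.status == STATUS_ALIVE
    ]
    if not colonies:
        raise EmptyPopulationError(
            f"population {survey.population_id} ({survey.year}) has no colonies "
            "after the inclusion filter"
        )
    return _mean_se([c.injury_total_pct for c in colonies])


def density(survey: PopulationSurvey) -> tuple[float, float | None]:
    """Mean density of living colonies (colonies per m²) across quadrats.

    Each quadrat contributes ``n_alive / area_m2``; the indicator is the
    mean of those per-quadrat densities with its standard error, so empty
    quadrats lower the mean.
    """
    per_quadrat = [q.n_alive / q.area_m2 for q in survey.quadrats]
    return _mean_se(per_quadrat)


def population_biomass(
    survey: PopulationSurvey, config: SpeciesConfig
) -> tuple[float, float | None]:
    """Mean live standing biomass (g per m²) across quadrats."""
    per_quadrat = [
        sum(_colony_live_biomass(c, config) for c in q.colonies if c.is_alive)
        / q.area_m2
        for q in survey.quadrats
    ]
    return _mean_se(per_quadrat)


def size_structure(
    survey: PopulationSurvey,
    config: SpeciesConfig,
    include_standing_dead: bool = False,
) -> dict[str, int]:
    """Colony counts per height class.

    The first class is closed ``[0, e1]``; every further class is
    left-open ``(e_i, e_{i+1}]`` and the last class is open-ended, so a
    boundary height belongs to the smaller class.
    """
    colonies = [
        c
        for c in survey.colonies
        if include_standing_dead or c.status == STATUS_ALIVE
    ]
    if not colonies:
        raise EmptyPopulationError(
            f"population {survey.population_id} ({survey.year}) has no colonies "
            "to bin"
        )
    edges = list(config.size_bins_cm[1:]) + [math.inf]
    labels = config.size_class_labels
    counts = dict.fromkeys(labels, 0)
    for c in colonies:
        k = next(i for i, e in enumerate(edges) if c.height_cm <= e)
        counts[labels[k]] += 1
    return counts


def _baseline_colony(c: ColonyRecord) -> ColonyRecord:
    status = (
        STATUS_STANDING_DEAD if abs(c.injury_old_pct - 100) <= _TOL else STATUS_ALIVE
    )
    return replace(c, injury_recent_pct=0.0, status=status)


def reconstruct_baseline(survey: PopulationSurvey) -> PopulationSurvey:
    """Estimate the pre-disturbance state from the injury classes.

    Old injuries are taken as already present before the event and kept;
    recent injuries are taken as healthy tissue before the event and
    zeroed.  A colony killed entirely by recent injury therefore returns
    to life in the baseline, while a colony with 100% old injury stays
    standing dead.  Idempotent by construction.
    """
    quadrats = [
        QuadratSurvey(
            quadrat_id=q.quadrat_id,
            area_m2=q.area_m2,
            colonies=tuple(_baseline_colony(c) for c in q.colonies),
        )
        for q in survey.quadrats
    ]
    return survey.with_quadrats(quadrats)


def _log_table_prob(table: np.ndarray, col_totals: np.ndarray, n1: int, n: int) -> np.ndarray:
    """Log point probability of 2xk tables (first row given) with fixed margins."""
    # P = prod_j C(c_j, x_j) / C(N, n1); gammaln keeps it stable for big counts
    logs = (
        special.gammaln(col_totals + 1)
        - special.gammaln(table + 1)
        - special.gammaln(col_totals - table + 1)
    )
    return logs.sum(axis=-1) - (
        special.gammaln(n + 1) - special.gammaln(n1 + 1) - special.gammaln(n - n1 + 1)
    )


def compare_size_structures(
    counts_a: Mapping[str, int] | Sequence[int],
    counts_b: Mapping[str, int] | Sequence[int],
    n_montecarlo: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test for a difference between two count vectors.

    Treats the two vectors as the rows of a 2xk contingency table and
    samples ``n_montecarlo`` tables with the observed margins held fixed
    (multivariate hypergeometric draws of the first row).  The p-value is
    ``(1 + #{tables with point probability <= observed}) /
    (n_montecarlo + 1)``, the add-one estimator of the exact
    probability-based Fisher test; deterministic given ``seed``.
    """
    if isinstance(counts_a, Mapping) or isinstance(counts_b, Mapping):
        if not (isinstance(counts_a, Mapping) and isinstance(counts_b, Mapping)):
            raise ValueError("both count vectors must use the same representation")
        if set(counts_a) != set(counts_b):
            raise ValueError(
                f"mismatched size-class bins: {sorted(counts_a)} vs {sorted(counts_b)}"
            )
        keys = list(counts_a)
        a = np.array([counts_a[k] for k in keys], dtype=np.int64)
        b = np.array([counts_b[k] for k in keys], dtype=np.int64)
    else:
        a = np.asarray(counts_a, dtype=np.int64)
        b = np.asarray(counts_b, dtype=np.int64)
        if a.shape != b.shape:
            raise ValueError(
                f"mismatched bin counts: {a.shape[0]} vs {b.shape[0]} classes"
            )
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    n1, n2 = int(a.sum()), int(b.sum())
    if n1 < 1 or n2 < 1:
        raise ValueError("both count vectors must total at least 1")

    col_totals = a + b
    keep = col_totals > 0
    a, cols = a[keep], col_totals[keep]
    n = n1 + n2

    obs_logp = _log_table_prob(a[None, :], cols, n1, n)[0]
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_hypergeometric(cols, n1, size=n_montecarlo)
    logp = _log_table_prob(samples, cols, n1, n)
    n_extreme = int((logp <= obs_logp + 1e-9).sum())
    return (1 + n_extreme) / (n_montecarlo + 1)


def compute_indicators(
    survey: PopulationSurvey,
    config: SpeciesConfig,
    include_standing_dead_injury: bool = True,
) -> IndicatorSet:
    """All five indicators for one survey."""
    inj_mean, inj_se = mean_injury(
        survey, include_standing_dead=include_standing_dead_injury
    )
    dens, dens_se = density(survey)
    biom, biom_se = population_biomass(survey, config)
    try:
        struct = size_structure(survey, config)
    except EmptyPopulationError:
        struct = dict.fromkeys(config.size_class_labels, 0)
    return IndicatorSet(
        population_id=survey.population_id,
        year=survey.year,
        pct_affected=pct_affected(survey, config),
        mean_injury_pct=inj_mean,
        mean_injury_se=inj_se,
        density_per_m2=dens,
        density_se=dens_se,
        biomass_g_per_m2=biom,
        biomass_se=biom_se,
        size_structure=struct,
        n_colonies=survey.n_colonies,
    )


def indicators_table(
    indicator_sets: Sequence[IndicatorSet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy long-form tables: (indicator values, size-structure counts)."""
    rows, size_rows = [], []
    for s in indicator_sets:
        base = dict(population=s.population_id, year=s.year, n=s.n_colonies)
        rows += [
            dict(base, indicator="pct_affected", value=s.pct_affected, se=np.nan),
            dict(
                base,
                indicator="mean_injury_pct",
                value=s.mean_injury_pct,
                se=np.nan if s.mean_injury_se is None else s.mean_injury_se,
            ),
            dict(
                base,
                indicator="density_per_m2",
                value=s.density_per_m2,
                se=np.nan if s.density_se is None else s.density_se,
            ),
            dict(
                base,
                indicator="biomass_g_per_m2",
                value=s.biomass_g_per_m2,
                se=np.nan if s.biomass_se is None else s.biomass_se,
            ),
        ]
        for label, count in s.size_structure.items():
            size_rows.append(
                dict(
                    population=s.population_id,
                    year=s.year,
                    size_class=label,
                    count=count,
                )
            )
    return pd.DataFrame(rows), pd.DataFrame(size_rows)
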