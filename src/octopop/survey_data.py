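"""Domain model, validation and I/O for colony-level quadrat surveys.

The unit of analysis is a :class:`PopulationSurvey`: every quadrat of one
population censused in one year.  Colonies carry two additive injury
classes — *recent* (denuded axis or fresh epibiosis) and *old*
(established overgrowth by epibionts) — whose sum is the total injured
fraction of the colony surface.  A colony whose surface is 100% injured
but whose skeleton is still attached is a *standing dead* colony; it is
retained in the survey (it is countable) while fully detached colonies
are simply absent.

Surveys are stored as plain CSV, one colony per row; a quadrat that
contains no colonies is encoded as a single row with ``status="absent"``
and blank colony fields so that empty quadrats still lower mean density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "STATUS_ALIVE",
    "STATUS_STANDING_DEAD",
    "ColonyRecord",
    "QuadratSurvey",
    "PopulationSurvey",
    "SpeciesConfig",
    "SurveySchemaError",
    "SurveyValidationError",
    "builtin_species_config",
    "load_species_config",
    "read_surveys",
    "write_surveys",
]

STATUS_ALIVE = "alive"
STATUS_STANDING_DEAD = "standing_dead"
_STATUS_ABSENT = "absent"  # CSV marker row for an empty quadrat, not a colony

REQUIRED_COLUMNS = (
    "population",
    "species",
    "year",
    "quadrat",
    "area_m2",
    "height_cm",
    "injury_recent_pct",
    "injury_old_pct",
    "status",
)

_TOL = 1e-9


class SurveySchemaError(ValueError):
    """Input table is missing required columns."""


class SurveyValidationError(ValueError):
    """A record violates a domain invariant; carries the offending row."""

    def __init__(self, message: str, row_index: int | None = None):
        if row_index is not None:
            message = f"row {row_index}: {message}"
        super().__init__(message)
        self.row_index = row_index


@dataclass(frozen=True)
class ColonyRecord:
    """One colony at one census."""

    colony_id: str
    height_cm: float
    injury_recent_pct: float
    injury_old_pct: float
    status: str = STATUS_ALIVE

    def __post_init__(self) -> None:
        if not self.height_cm > 0:
            raise SurveyValidationError(
                f"colony {self.colony_id}: height_cm must be > 0, got {self.height_cm}"
            )
        for name, v in (
            ("injury_recent_pct", self.injury_recent_pct),
            ("injury_old_pct", self.injury_old_pct),
        ):
            if not (0 <= v <= 100):
                raise SurveyValidationError(
                    f"colony {self.colony_id}: {name} must be in [0, 100], got {v}"
                )
        if self.injury_total_pct > 100 + _TOL:
            raise SurveyValidationError(
                f"colony {self.colony_id}: injury_recent_pct + injury_old_pct = "
                f"{self.injury_total_pct:g} exceeds the 100% bound"
            )
        if self.status not in (STATUS_ALIVE, STATUS_STANDING_DEAD):
            raise SurveyValidationError(
                f"colony {self.colony_id}: unknown status {self.status!r} "
                f"(expected {STATUS_ALIVE!r} or {STATUS_STANDING_DEAD!r})"
            )
        fully_injured = abs(self.injury_total_pct - 100) <= _TOL
        if fully_injured and self.status != STATUS_STANDING_DEAD:
            raise SurveyValidationError(
                f"colony {self.colony_id}: 100% injured colony must have "
                f"status {STATUS_STANDING_DEAD!r}"
            )
        if not fully_injured and self.status == STATUS_STANDING_DEAD:
            raise SurveyValidationError(
                f"colony {self.colony_id}: {STATUS_STANDING_DEAD!r} requires "
                f"total injury = 100%, got {self.injury_total_pct:g}"
            )

    @property
    def injury_total_pct(self) -> float:
        return self.injury_recent_pct + self.injury_old_pct

    @property
    def is_alive(self) -> bool:
        return self.status == STATUS_ALIVE


@dataclass(frozen=True)
class QuadratSurvey:
    """All colonies censused inside one fixed-area sampling frame."""

    quadrat_id: str
    area_m2: float
    colonies: tuple[ColonyRecord, ...] = ()

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise SurveyValidationError(
                f"quadrat {self.quadrat_id}: area_m2 must be > 0, got {self.area_m2}"
            )
        object.__setattr__(self, "colonies", tuple(self.colonies))
        ids = [c.colony_id for c in self.colonies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SurveyValidationError(
                f"quadrat {self.quadrat_id}: duplicate colony ids {dup}"
            )

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def n_alive(self) -> int:
        return sum(1 for c in self.colonies if c.is_alive)


@dataclass(frozen=True)
class PopulationSurvey:
    """One population in one census year: the unit indicators act on."""

    population_id: str
    species: str
    year: int
    quadrats: tuple[QuadratSurvey, ...]
    depth_m: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "quadrats", tuple(self.quadrats))
        if not self.quadrats:
            raise SurveyValidationError(
                f"population {self.population_id} ({self.year}): "
                "must contain at least one quadrat"
            )
        ids = [q.quadrat_id for q in self.quadrats]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SurveyValidationError(
                f"population {self.population_id} ({self.year}): "
                f"duplicate quadrat ids {dup}"
            )

    @property
    def colonies(self) -> tuple[ColonyRecord, ...]:
        return tuple(c for q in self.quadrats for c in q.colonies)

    @property
    def n_colonies(self) -> int:
        return sum(q.n_colonies for q in self.quadrats)

    @property
    def total_area_m2(self) -> float:
        return sum(q.area_m2 for q in self.quadrats)

    def with_quadrats(self, quadrats: Iterable[QuadratSurvey]) -> "PopulationSurvey":
        return replace(self, quadrats=tuple(quadrats))


@dataclass(frozen=True)
class SpeciesConfig:
    """Species-level constants: allometry, size bins and thermal floors.

    Biomass of a fully healthy colony of height H cm is
    ``allometric_a * H ** allometric_b`` grams.  ``size_bins_cm`` are the
    finite bin edges; the last class is open-ended.
    """

    species: str
    allometric_a: float
    allometric_b: float
    size_bins_cm: tuple[float, ...]
    affected_threshold_pct: float = 10.0
    sublethal_temp_c: float = 23.0
    lethal_temp_c: float = 25.0

    def __post_init__(self) -> None:
        if not self.allometric_a > 0:
            raise ValueError(f"allometric_a must be > 0, got {self.allometric_a}")
        if not self.allometric_b > 0:
            raise ValueError(f"allometric_b must be > 0, got {self.allometric_b}")
        edges = tuple(float(e) for e in self.size_bins_cm)
        if not edges or edges[0] != 0:
            raise ValueError("size_bins_cm must start at 0")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"size_bins_cm must be strictly increasing, got {edges}")
        object.__setattr__(self, "size_bins_cm", edges)
        if not (0 < self.affected_threshold_pct < 100):
            raise ValueError(
                "affected_threshold_pct must be in (0, 100), "
                f"got {self.affected_threshold_pct}"
            )

    @property
    def size_class_labels(self) -> tuple[str, ...]:
        edges = self.size_bins_cm
        labels = [f"{edges[0]:g}-{edges[1]:g}"]
        labels += [f">{a:g}-{b:g}" for a, b in zip(edges[1:], edges[2:])]
        labels.append(f">{edges[-1]:g}")
        return tuple(labels)


_BUILTIN_CONFIGS = {
    "paramuricea_clavata": dict(
        allometric_a=0.002,
        allometric_b=2.61,
        size_bins_cm=(0.0, 10.0, 20.0, 30.0, 40.0),
    ),
    "corallium_rubrum": dict(
        allometric_a=0.1535,
        allometric_b=1.9732,
        size_bins_cm=(0.0, 3.0, 6.0, 9.0, 15.0),
    ),
}


def builtin_species_config(species: str) -> SpeciesConfig:
    """Return the shipped configuration for one of the study species."""
    try:
        params = _BUILTIN_CONFIGS[species]
    except KeyError:
        known = ", ".join(sorted(_BUILTIN_CONFIGS))
        raise ValueError(
            f"unknown species {species!r}; supported species: {known}"
        ) from None
    return SpeciesConfig(species=species, **params)


def load_species_config(path: str | Path) -> SpeciesConfig:
    """Load a SpeciesConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of SpeciesConfig fields")
    data = dict(data)
    data["size_bins_cm"] = tuple(data["size_bins_cm"])
    return SpeciesConfig(**data)


def _parse_row(row: pd.Series, idx: int) -> ColonyRecord:
    try:
        return ColonyRecord(
            colony_id=str(row["colony_id"]),
            height_cm=float(row["height_cm"]),
            injury_recent_pct=float(row["injury_recent_pct"]),
            injury_old_pct=float(row["injury_old_pct"]),
            status=str(row["status"]),
        )
    except SurveyValidationError as exc:
        raise SurveyValidationError(str(exc), row_index=idx) from None


def read_surveys(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[PopulationSurvey]:
    """Read a colony-per-row CSV into validated surveys.

    Parameters
    ----------
    path
        CSV with header row and the columns of ``REQUIRED_COLUMNS`` (plus
        optional ``colony_id`` and ``depth_m``).
    schema
        Optional mapping from required column name to the actual column
        name in the file, for ingesting foreign tables.

    Returns
    -------
    One :class:`PopulationSurvey` per (population, year) group, sorted by
    population id then year.  Empty quadrats (rows with status
    ``absent``) are preserved as quadrats with zero colonies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    df = pd.read_csv(path, dtype={"status": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveySchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if "colony_id" not in df.columns:
        df["colony_id"] = [f"c{i}" for i in range(len(df))]
    if "depth_m" not in df.columns:
        df["depth_m"] = math.nan

    surveys: list[PopulationSurvey] = []
    for (pop, year), group in df.groupby(["population", "year"], sort=True):
        species = group["species"].iloc[0]
        if (group["species"] != species).any():
            raise SurveyValidationError(
                f"population {pop} ({year}): quadrats report multiple species"
            )
        depth = group["depth_m"].iloc[0]
        quadrats = []
        for quad, qgroup in group.groupby("quadrat", sort=True):
            area = float(qgroup["area_m2"].iloc[0])
            colonies = []
            for idx, row in qgroup.iterrows():
                if str(row["status"]).strip().lower() == _STATUS_ABSENT:
                    continue
                colonies.append(_parse_row(row, idx))
            quadrats.append(
                QuadratSurvey(quadrat_id=str(quad), area_m2=area, colonies=colonies)
            )
        surveys.append(
            PopulationSurvey(
                population_id=str(pop),
                species=str(species),
                year=int(year),
                quadrats=tuple(quadrats),
                depth_m=None if pd.isna(depth) else float(depth),
            )
        )
    return surveys


def write_surveys(surveys: Sequence[PopulationSurvey], path: str | Path) -> None:
    """Write surveys to CSV in the schema consumed by :func:`read_surveys`."""
    rows = []
    for s in surveys:
        for q in s.quadrats:
            if not q.colonies:
                rows.append(
                    dict(
                        population=s.population_id,
                        species=s.species,
                        year=s.year,
                        depth_m=s.depth_m,
                        quadrat=q.quadrat_id,
                        area_m2=q.area_m2,
                        colony_id="",
                        height_cm="",
                        injury_recent_pct="",
                        injury_old_pct="",
                        status=_STATUS_ABSENT,
                    )
                )
            for c in q.colonies:
                rows.append(
                    dict(
                        population=s.population_id,
                        species=s.species,
                        year=s.year,
                        depth_m=s.depth_m,
                        quadrat=q.quadrat_id,
                        area_m2=q.area_m2,
                        colony_id=c.colony_id,
                        height_cm=repr(c.height_cm),
                        injury_recent_pct=repr(c.injury_recent_pct),
                        injury_old_pct=repr(c.injury_old_pct),
                        status=c.status,
                    )
                )
    pd.DataFrame(rows).to_csv(path, index=False)
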