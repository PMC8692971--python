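import pytest

from octopop.survey_data import (
    ColonyRecord,
    PopulationSurvey,
    QuadratSurvey,
    builtin_species_config,
)


def make_colony(cid="c1", height=10.0, recent=0.0, old=0.0, status=None):
    if status is None:
        status = "standing_dead" if abs(recent + old - 100) <= 1e-9 else "alive"
    return ColonyRecord(
        colony_id=cid,
        height_cm=height,
        injury_recent_pct=recent,
        injury_old_pct=old,
        status=status,
    )


def make_survey(colonies_by_quadrat, area=0.25, species="paramuricea_clavata",
                population="pop", year=2004):
    quadrats = [
        QuadratSurvey(quadrat_id=f"q{i}", area_m2=area, colonies=tuple(cols))
        for i, cols in enumerate(colonies_by_quadrat)
    ]
    return PopulationSurvey(
        population_id=population, species=species, year=year,
        quadrats=tuple(quadrats),
    )


@pytest.fixture
def pclavata_config():
    return builtin_species_config("paramuricea_clavata")


@pytest.fixture
def crubrum_config():
    return builtin_species_config("corallium_rubrum")
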