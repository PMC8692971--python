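import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats

from octopop.indicators import (
    EmptyPopulationError,
    colony_biomass,
    compare_size_structures,
    compute_indicators,
    density,
    indicators_table,
    mean_injury,
    pct_affected,
    population_biomass,
    reconstruct_baseline,
    size_structure,
)
from octopop.survey_data import QuadratSurvey, builtin_species_config

PCLAVATA = builtin_species_config("paramuricea_clavata")

from conftest import make_colony, make_survey


def injuries_survey(injuries, **kwargs):
    """One quadrat, one colony per injury percentage."""
    return make_survey(
        [[make_colony(f"c{i}", recent=inj, old=0.0) for i, inj in enumerate(injuries)]],
        **kwargs,
    )


class TestColonyBiomass:
    def test_pclavata_coefficient(self, pclavata_config):
        assert colony_biomass(1.0, 0.0, pclavata_config) == pytest.approx(0.002)

    def test_crubrum_coefficient(self, crubrum_config):
        assert colony_biomass(1.0, 0.0, crubrum_config) == pytest.approx(0.1535)

    def test_fully_injured_is_zero(self, pclavata_config, crubrum_config):
        for cfg in (pclavata_config, crubrum_config):
            assert colony_biomass(37.2, 100.0, cfg) == 0.0

    def test_half_injured_10cm(self, pclavata_config):
        # independent scalar evaluation of a * H**b * live fraction
        expected = 0.5 * 0.002 * 10**2.61
        assert colony_biomass(10.0, 50.0, pclavata_config) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("height, injury", [(-1, 0), (0, 0), (5, -1), (5, 101)])
    def test_domain_errors(self, height, injury, pclavata_config):
        with pytest.raises(ValueError):
            colony_biomass(height, injury, pclavata_config)

    @given(
        h=st_.floats(0.01, 200.0),
        dh=st_.floats(0.01, 50.0),
        inj=st_.floats(0.0, 99.0),
        dinj=st_.floats(0.1, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_property(self, h, dh, inj, dinj):
        cfg = PCLAVATA
        assert colony_biomass(h + dh, inj, cfg) > colony_biomass(h, inj, cfg)
        if inj + dinj <= 100:
            assert colony_biomass(h, inj + dinj, cfg) < colony_biomass(h, inj, cfg)


class TestPctAffected:
    def test_strict_threshold(self, pclavata_config):
        survey = injuries_survey([5, 10, 10.1, 50])
        assert pct_affected(survey, pclavata_config) == pytest.approx(50.0)

    def test_all_healthy(self, pclavata_config):
        assert pct_affected(injuries_survey([0, 0, 0]), pclavata_config) == 0.0

    def test_all_standing_dead(self, pclavata_config):
        assert pct_affected(injuries_survey([100, 100]), pclavata_config) == 100.0

    def test_empty_population_error(self, pclavata_config):
        with pytest.raises(EmptyPopulationError):
            pct_affected(make_survey([[]]), pclavata_config)

    def test_kind_selection(self, pclavata_config):
        survey = make_survey([[make_colony("a", recent=50, old=5),
                               make_colony("b", recent=5, old=50)]])
        assert pct_affected(survey, pclavata_config, "recent") == 50.0
        assert pct_affected(survey, pclavata_config, "old") == 50.0
        assert pct_affected(survey, pclavata_config, "any") == 100.0

    @given(st_.lists(st_.floats(0, 100), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_any_dominates_kinds(self, injuries):
        survey = injuries_survey(injuries)
        any_ = pct_affected(survey, PCLAVATA, "any")
        assert any_ >= pct_affected(survey, PCLAVATA, "recent")
        assert any_ >= pct_affected(survey, PCLAVATA, "old")


class TestMeanInjury:
    def test_hand_mean(self):
        mean, se = mean_injury(injuries_survey([0, 50, 100]))
        assert mean == pytest.approx(50.0)
        assert se == pytest.approx(np.std([0, 50, 100], ddof=1) / math.sqrt(3))

    def test_all_zero(self):
        assert mean_injury(injuries_survey([0, 0]))[0] == 0.0

    def test_single_colony_se_missing(self):
        mean, se = mean_injury(injuries_survey([20]))
        assert mean == 20.0
        assert se is None

    def test_exclude_standing_dead(self):
        survey = injuries_survey([0, 50, 100])
        mean, _ = mean_injury(survey, include_standing_dead=False)
        assert mean == pytest.approx(25.0)

    def test_empty_after_filter(self):
        with pytest.raises(EmptyPopulationError):
            mean_injury(injuries_survey([100, 100]), include_standing_dead=False)


class TestDensity:
    def test_two_quadrat_mean(self):
        survey = make_survey(
            [[make_colony(f"a{i}") for i in range(5)],
             [make_colony(f"b{i}") for i in range(10)]],
            area=0.25,
        )
        mean, se = density(survey)
        assert mean == pytest.approx(30.0)  # (20 + 40) / 2
        assert se == pytest.approx(np.std([20, 40], ddof=1) / math.sqrt(2))

    def test_all_empty(self):
        assert density(make_survey([[], [], []]))[0] == 0.0

    def test_standing_dead_excluded(self):
        survey = make_survey([[make_colony("a"), make_colony("b", recent=100)]],
                             area=0.25)
        assert density(survey)[0] == pytest.approx(4.0)

    def test_duplication_identity(self):
        survey = make_survey(
            [[make_colony(f"a{i}") for i in range(5)],
             [make_colony(f"b{i}") for i in range(10)]]
        )
        doubled = survey.with_quadrats(
            list(survey.quadrats)
            + [QuadratSurvey(f"dup-{q.quadrat_id}", q.area_m2,
                             tuple(make_colony(f"d{q.quadrat_id}{i}")
                                   for i in range(q.n_colonies)))
               for q in survey.quadrats]
        )
        m1, se1 = density(survey)
        m2, se2 = density(doubled)
        assert m2 == pytest.approx(m1)
        # with the ddof=1 sample sd, duplicating n quadrats scales the se by
        # sqrt((n-1)/(2n-1)); here n=2, approaching 1/sqrt(2) for large n
        n = len(survey.quadrats)
        assert se2 == pytest.approx(se1 * math.sqrt((n - 1) / (2 * n - 1)))

    @given(factor=st_.integers(2, 5))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, factor):
        # scaling every quadrat area and colony count together leaves density fixed
        base = make_survey(
            [[make_colony(f"a{i}") for i in range(4)],
             [make_colony(f"b{i}") for i in range(7)]],
            area=0.25,
        )
        scaled = base.with_quadrats(
            QuadratSurvey(
                q.quadrat_id,
                q.area_m2 * factor,
                tuple(make_colony(f"{q.quadrat_id}s{i}")
                      for i in range(q.n_colonies * factor)),
            )
            for q in base.quadrats
        )
        assert density(scaled)[0] == pytest.approx(density(base)[0])


class TestPopulationBiomass:
    def test_single_healthy_colony(self, pclavata_config):
        survey = make_survey([[make_colony("a", height=1.0)]], area=0.25)
        mean, se = population_biomass(survey, pclavata_config)
        assert mean == pytest.approx(0.008)  # 0.002 g / 0.25 m2
        assert se is None

    def test_empty_survey(self, pclavata_config):
        assert population_biomass(make_survey([[], []]), pclavata_config)[0] == 0.0

    def test_fully_injured_population(self, pclavata_config):
        survey = injuries_survey([100, 100])
        assert population_biomass(survey, pclavata_config)[0] == 0.0


class TestSizeStructure:
    def test_one_per_class(self, pclavata_config):
        survey = make_survey([[make_colony(f"c{h}", height=h)
                               for h in (5, 15, 25, 35, 45)]])
        counts = size_structure(survey, pclavata_config)
        assert all(v == 1 for v in counts.values())

    def test_boundary_belongs_left(self, pclavata_config):
        survey = make_survey([[make_colony("c", height=10.0)]])
        counts = size_structure(survey, pclavata_config)
        assert counts["0-10"] == 1
        assert counts[">10-20"] == 0

    def test_crubrum_15cm(self, crubrum_config):
        survey = make_survey([[make_colony("c", height=15.0)]],
                             species="corallium_rubrum")
        assert size_structure(survey, crubrum_config)[">9-15"] == 1

    def test_open_last_bin(self, pclavata_config):
        survey = make_survey([[make_colony("c", height=500.0)]])
        assert size_structure(survey, pclavata_config)[">40"] == 1

    @given(st_.lists(st_.floats(0.1, 100), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_counts_conserve_colonies(self, heights):
        survey = make_survey([[make_colony(f"c{i}", height=h)
                               for i, h in enumerate(heights)]])
        counts = size_structure(survey, PCLAVATA)
        assert sum(counts.values()) == len(heights)


class TestReconstructBaseline:
    def test_recent_removed_old_kept(self):
        survey = make_survey([[make_colony("c", recent=30, old=20)]])
        base = reconstruct_baseline(survey)
        c = base.colonies[0]
        assert c.injury_recent_pct == 0
        assert c.injury_old_pct == 20
        assert c.injury_total_pct == 20

    def test_fully_recent_dead_resurrects(self):
        survey = make_survey([[make_colony("c", recent=100, old=0)]])
        c = reconstruct_baseline(survey).colonies[0]
        assert c.status == "alive"
        assert c.injury_total_pct == 0

    def test_fully_old_dead_stays_dead(self):
        survey = make_survey([[make_colony("c", recent=0, old=100)]])
        assert reconstruct_baseline(survey).colonies[0].status == "standing_dead"

    def test_idempotent(self):
        survey = make_survey(
            [[make_colony("a", recent=30, old=20),
              make_colony("b", recent=100),
              make_colony("c", old=100)]]
        )
        once = reconstruct_baseline(survey)
        assert reconstruct_baseline(once) == once

    @given(
        st_.lists(
            st_.tuples(st_.floats(0, 100), st_.floats(0, 100)).filter(
                lambda t: t[0] + t[1] <= 100
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_baseline_consistency(self, injuries):
        survey = make_survey(
            [[make_colony(f"c{i}", recent=r, old=o)
              for i, (r, o) in enumerate(injuries)]]
        )
        base = reconstruct_baseline(survey)
        assert mean_injury(base)[0] <= mean_injury(survey)[0] + 1e-9
        assert density(base)[0] >= density(survey)[0] - 1e-9


class TestCompareSizeStructures:
    def test_identical_counts(self):
        p = compare_size_structures([30, 20, 10], [30, 20, 10], 10_000, seed=1)
        assert p >= 0.99

    def test_disjoint_counts(self):
        p = compare_size_structures([50, 0], [0, 50], 10_000, seed=1)
        assert p <= 0.001

    def test_2x2_matches_fisher_oracle(self):
        table = [[12, 5], [6, 14]]
        exact = stats.fisher_exact(table)[1]
        n = 20_000
        p = compare_size_structures(table[0], table[1], n, seed=7)
        mc_se = math.sqrt(exact * (1 - exact) / n)
        assert abs(p - exact) <= 3 * mc_se + 2 / n

    def test_deterministic_under_seed(self):
        a, b = [10, 2, 8], [3, 9, 4]
        assert compare_size_structures(a, b, 2000, seed=5) == compare_size_structures(
            a, b, 2000, seed=5
        )

    def test_mismatched_bins_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_size_structures([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="mismatch"):
            compare_size_structures({"a": 1, "b": 2}, {"a": 1, "c": 2})

    def test_dict_input(self):
        p = compare_size_structures({"s": 25, "m": 25}, {"s": 25, "m": 25},
                                    5000, seed=0)
        assert p >= 0.99

    def test_empty_vector_error(self):
        with pytest.raises(ValueError, match="at least 1"):
            compare_size_structures([0, 0], [1, 2])


class TestIndicatorSetAndTable:
    def test_compute_indicators_consistency(self, pclavata_config):
        survey = make_survey(
            [[make_colony("a", height=12, recent=20),
              make_colony("b", height=25, recent=100)],
             [make_colony("c", height=8)]],
        )
        s = compute_indicators(survey, pclavata_config)
        assert sum(s.size_structure.values()) == 2  # alive colonies binned
        assert 0 <= s.pct_affected <= 100
        assert s.density_per_m2 >= 0
        assert s.biomass_g_per_m2 >= 0
        assert s.n_colonies == 3

    def test_tidy_tables(self, pclavata_config):
        survey = make_survey([[make_colony("a", height=12)]])
        values, sizes = indicators_table([compute_indicators(survey, pclavata_config)])
        assert set(values.columns) == {"population", "year", "n", "indicator",
                                       "value", "se"}
        assert set(values["indicator"]) == {
            "pct_affected", "mean_injury_pct", "density_per_m2", "biomass_g_per_m2"
        }
        assert set(sizes.columns) == {"population", "year", "size_class", "count"}
        assert sizes["count"].sum() == 1
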