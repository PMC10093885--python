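import pytest
from hypothesis import given, settings, strategies as st

from mednova import NutrientPanel, fsam_nps, grade
from mednova.errors import ConfigurationError
from mednova.nutriscore import (
    ComponentTable,
    MissingNegativeNutrient,
    component_points,
    default_score_tables,
    negative_points,
    positive_points,
)

from conftest import make_food


class TestComponentPoints:
    def test_zero_scores_zero(self, tables):
        for table in tables.solid.values():
            assert component_points(0.0, table) == 0

    def test_saturation_at_max(self, tables):
        for table in tables.solid.values():
            assert component_points(table.thresholds[-1] + 1, table) == table.points[-1]

    def test_boundary_takes_lower_band(self, tables):
        sugars = tables.solid["sugars_g"]
        assert component_points(4.5, sugars) == 0
        assert component_points(4.5001, sugars) == 1

    def test_egg_energy_is_zero_points(self, tables):
        # 46 kcal = 192.464 kJ, below the first solid energy threshold
        assert component_points(192.464, tables.solid["energy_kj"]) == 0

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            ComponentTable((2.0, 1.0), (0, 1, 2))


class TestNegativePositive:
    def test_all_zero_panel(self, tables):
        panel = NutrientPanel(energy_kcal=0, sugars_g=0, sfa_g=0, salt_g=0, total_fat_g=0)
        n, breakdown = negative_points(panel, "solid", tables)
        assert n == 0 and set(breakdown.values()) == {0}

    def test_saturated_panel_scores_40(self, tables):
        panel = NutrientPanel(energy_kcal=1000, sugars_g=50, sfa_g=11, salt_g=2.5,
                              total_fat_g=50)
        n, _ = negative_points(panel, "solid", tables)
        assert n == 40

    def test_egg_negative_points(self, tables):
        panel = NutrientPanel(energy_kcal=46, sugars_g=0.3, sfa_g=0.0, salt_g=0.44,
                              total_fat_g=0.3, protein_g=11.0)
        n, breakdown = negative_points(panel, "solid", tables)
        assert n == 1
        assert breakdown == {"energy_kj": 0, "sugars_g": 0, "sfa_g": 0, "sodium_mg": 1}

    def test_missing_negative_raises(self, tables):
        panel = NutrientPanel(energy_kcal=100, sfa_g=0, salt_g=0)  # sugars missing
        with pytest.raises(MissingNegativeNutrient, match="sugars"):
            negative_points(panel, "solid", tables)

    def test_positive_saturated(self, tables):
        panel = NutrientPanel(protein_g=10, fiber_g=5, fv_percent=100)
        p, _ = positive_points(panel, "solid", tables)
        assert p == 15

    def test_protein_only(self, tables):
        panel = NutrientPanel(protein_g=11.0, fiber_g=0, fv_percent=0)
        p, breakdown = positive_points(panel, "solid", tables)
        assert p == 5 and breakdown["protein_g"] == 5


class TestFsamNps:
    def test_egg_worked_example(self, egg_food, tables):
        r = fsam_nps(egg_food, tables)
        assert r.status == "scored"
        assert r.score == -4
        assert r.grade == "A"
        assert set(r.imputed_fields) == {"fiber_g", "fv_percent"}

    def test_all_zero_solid_grades_b(self, tables):
        food = make_food(panel=NutrientPanel(energy_kcal=0, sugars_g=0, sfa_g=0,
                                             salt_g=0, total_fat_g=0))
        r = fsam_nps(food, tables)
        assert (r.negative_points, r.positive_points, r.score, r.grade) == (0, 0, 0, "B")

    def test_missing_sugars_excluded(self, tables):
        food = make_food(panel=NutrientPanel(energy_kcal=100, sfa_g=0, salt_g=0))
        r = fsam_nps(food, tables)
        assert r.status == "excluded_missing_negative"
        assert r.score is None and r.grade is None
        assert "sugars_g" in r.missing_negative

    def test_full_rule_drops_protein_at_high_n(self):
        full = default_score_tables(mode="full_rule")
        paper = default_score_tables()
        panel = NutrientPanel(energy_kcal=500, sugars_g=20, sfa_g=5, salt_g=0,
                              total_fat_g=20, protein_g=10, fiber_g=0, fv_percent=0)
        snack = make_food(subcategory="Savoury Snack", panel=panel)
        cheese = make_food(subcategory="Cheese", panel=panel)
        assert fsam_nps(snack, paper).score == 9  # N=14, P=5
        assert fsam_nps(snack, full).score == 14  # protein not counted
        assert fsam_nps(cheese, full).score == 9  # cheese keeps protein

    def test_exclusion_count_matches_missing_negatives(self, tables):
        from mednova import default_config, generate_db
        from mednova.food_model import NEGATIVE_NUTRIENTS

        foods, _ = generate_db(default_config(seed=5))
        results = [fsam_nps(f, tables) for f in foods]
        n_excluded = sum(r.status == "excluded_missing_negative" for r in results)
        n_missing = sum(bool(f.panel.missing(NEGATIVE_NUTRIENTS)) for f in foods)
        assert n_excluded == n_missing


class TestGrade:
    SOLID_MAP = {**{s: "A" for s in range(-15, 0)},
                 **{s: "B" for s in range(0, 3)},
                 **{s: "C" for s in range(3, 11)},
                 **{s: "D" for s in range(11, 19)},
                 **{s: "E" for s in range(19, 41)}}
    BEVERAGE_MAP = {**{s: "B" for s in range(-15, 2)},
                    **{s: "C" for s in range(2, 6)},
                    **{s: "D" for s in range(6, 10)},
                    **{s: "E" for s in range(10, 41)}}

    def test_solid_interval_map(self):
        for s in range(-15, 41):
            assert grade(s, "solid") == self.SOLID_MAP[s]

    def test_beverage_interval_map(self):
        for s in range(-15, 41):
            assert grade(s, "beverage") == self.BEVERAGE_MAP[s]

    def test_water_always_a(self):
        for s in (-15, 0, 10, 40):
            assert grade(s, "beverage", is_water=True) == "A"

    @pytest.mark.parametrize("score,basis,letter",
                             [(-5, "solid", "A"), (1, "beverage", "B"),
                              (10, "beverage", "E"), (19, "solid", "E")])
    def test_printed_boundaries(self, score, basis, letter):
        assert grade(score, basis) == letter

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade(-16, "solid")
        with pytest.raises(ValueError):
            grade(41, "solid")


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

_panel_values = dict(
    energy_kcal=st.floats(0, 900), sugars_g=st.floats(0, 100),
    sfa_g=st.floats(0, 30), salt_g=st.floats(0, 10),
    protein_g=st.floats(0, 40), fiber_g=st.floats(0, 30), fv_percent=st.floats(0, 100),
)


@given(st.fixed_dictionaries(_panel_values),
       st.sampled_from(["solid", "beverage"]),
       st.sampled_from(["paper_subtraction", "full_rule"]))
@settings(derandomize=True, max_examples=150)
def test_score_bounds_and_monotonicity(values, basis, mode):
    """N in 0..40, P in 0..15, S integer in -15..40; S monotone per nutrient."""
    tables = default_score_tables(mode=mode)
    panel = NutrientPanel(total_fat_g=max(30.0, values["sfa_g"]), **values)
    food = make_food(basis=basis, panel=panel)
    r = fsam_nps(food, tables)
    assert 0 <= r.negative_points <= 40
    assert 0 <= r.positive_points <= 15
    assert -15 <= r.score <= 40
    assert isinstance(r.score, int)

    # more sugars never lowers the score; more fiber never raises it
    worse = NutrientPanel(**{**values, "total_fat_g": panel.total_fat_g,
                             "sugars_g": min(100.0, values["sugars_g"] + 10)})
    better = NutrientPanel(**{**values, "total_fat_g": panel.total_fat_g,
                              "fiber_g": values["fiber_g"] + 5})
    assert fsam_nps(make_food(basis=basis, panel=worse), tables).score >= r.score
    assert fsam_nps(make_food(basis=basis, panel=better), tables).score <= r.score
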