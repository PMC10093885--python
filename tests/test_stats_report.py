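import numpy as np
import pytest
from scipy import stats as sps

from mednova import (
    classify_all,
    kruskal_wallis,
    mann_whitney_u,
    median_iqr,
    nova_distribution_table,
    nutrient_comparison_table,
    nutriscore_distribution_table,
    score_all,
    tier_nova_crosstab,
)
from mednova.errors import NotApplicable
from mednova.nova import NovaAssignment
from mednova.nutriscore import FSAmNPSResult
from mednova.pyramid import TierAssignment
from mednova.stats_report import bonferroni

from conftest import make_food


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5], (5, 5, 5)),
            ([1, 2, 3, 4, 5], (3, 1.5, 4.5)),
            ([1, 2, 3, 4], (2.5, 1.25, 3.75)),
        ],
    )
    def test_weighted_average_quantiles(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_centre(self):
        a = [1, 2, 3, 4, 5]
        u, p = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.95

    def test_small_group_not_applicable(self):
        with pytest.raises(NotApplicable):
            mann_whitney_u([1], [2, 3])

    def test_exact_and_normal_branches_agree_at_crossover(self):
        # combined n = 12 uses enumeration; the tie-corrected normal
        # approximation must agree closely at that size
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            _, p_exact = mann_whitney_u(a, b)
            p_normal = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_normal) <= 0.02


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1)

    def test_degenerate_constant_groups(self):
        h, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7)
        assert p == pytest.approx(float(sps.chi2.sf(32 / 7, 2)))

    def test_two_groups_equal_squared_mw_z(self):
        # with two groups, tie-corrected H equals the square of the
        # Mann-Whitney z statistic (no continuity correction)
        rng = np.random.default_rng(1)
        a = np.round(rng.normal(0, 1, 30), 1)  # rounding induces ties
        b = np.round(rng.normal(0.4, 1, 25), 1)
        h, p_kw = kruskal_wallis([a, b])
        p_mw = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        z = sps.norm.isf(p_mw / 2)
        assert h == pytest.approx(z**2, rel=1e-6)

    def test_undersized_group_not_applicable(self):
        with pytest.raises(NotApplicable):
            kruskal_wallis([[1, 2], [3]])


def test_bonferroni_caps_at_one():
    assert bonferroni(0.02, 3) == pytest.approx(0.06)
    assert bonferroni(0.6, 3) == 1.0
    with pytest.raises(ValueError):
        bonferroni(0.5, 0)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def _assignments(counts: dict[str, int]) -> list[NovaAssignment]:
    out, k = [], 0
    for group, n in counts.items():
        for _ in range(n):
            out.append(NovaAssignment(f"f{k}", group, (), "test"))
            k += 1
    return out


def _tiers(assignments, pyramid="tMDP", tier="T"):
    return [TierAssignment(a.food_id, pyramid, "assigned", tier) for a in assignments]


class TestNovaDistribution:
    def test_scope_percentages(self):
        counts = {"NOVA1": 604, "NOVA2": 34, "NOVA3": 164, "NOVA4": 565}
        asg = _assignments(counts)
        table = nova_distribution_table(asg, {"tMDP": _tiers(asg)}).data
        row = table[table["scope"] == "tMDP"].iloc[0]
        assert row["n"] == 1367
        assert (row["NOVA1_pct"], row["NOVA2_pct"], row["NOVA3_pct"], row["NOVA4_pct"]) \
            == (44.2, 2.5, 12.0, 41.3)

    def test_unclassifiable_excluded_from_denominator(self):
        asg = _assignments({"NOVA1": 10, "UNCLASSIFIABLE": 5})
        table = nova_distribution_table(asg).data
        row = table.iloc[0]
        assert row["n"] == 10 and row["NOVA1_pct"] == 100.0

    def test_empty_scope(self):
        table = nova_distribution_table([]).data
        assert table.iloc[0]["n"] == 0
        assert table.iloc[0]["NOVA1_pct"] == 0.0


class TestCrosstab:
    def test_row_counts_and_percentages(self):
        foods = [make_food(id=f"c{i}", subcategory="Cheese") for i in range(4)]
        asg = [NovaAssignment(f.id, g, (), "t")
               for f, g in zip(foods, ["NOVA3", "NOVA3", "NOVA3", "NOVA4"])]
        tiers = [TierAssignment(f.id, "tMDP", "assigned", "Dairy") for f in foods]
        table = tier_nova_crosstab(foods, asg, tiers, by_subcategory=True).data
        row = table.iloc[0]
        assert (row["tier"], row["subcategory"], row["n"]) == ("Dairy", "Cheese", 4)
        assert (row["NOVA3_n"], row["NOVA3_pct"]) == (3, 75.0)
        assert (row["NOVA4_n"], row["NOVA4_pct"]) == (1, 25.0)
        assert row[[f"{g}_n" for g in ("NOVA1", "NOVA2", "NOVA3", "NOVA4")]].sum() == 4

    def test_empty_tiers_omitted(self):
        foods = [make_food(id="x", subcategory="Pulses")]
        asg = [NovaAssignment("x", "NOVA1", (), "t")]
        tiers = [TierAssignment("x", "tMDP", "assigned", "Olives, Pulses, Nuts")]
        table = tier_nova_crosstab(foods, asg, tiers).data
        assert list(table["tier"]) == ["Olives, Pulses, Nuts"]


def _scored_foods(values, tier="T", subcategory="Cheese", groups=None):
    """Foods with fixed scores wired straight into result objects."""
    foods, asg, tiers, scores = [], [], [], []
    for i, v in enumerate(values):
        fid = f"s{i}"
        foods.append(make_food(id=fid, subcategory=subcategory))
        asg.append(NovaAssignment(fid, (groups or ["NOVA4"] * len(values))[i], (), "t"))
        tiers.append(TierAssignment(fid, "tMDP", "assigned", tier))
        from mednova.nutriscore import grade as grade_fn

        scores.append(FSAmNPSResult(fid, "scored", 0, {}, 0, {}, v,
                                    grade_fn(v, "solid"), ()))
    return foods, asg, tiers, scores


class TestNutriscoreDistribution:
    def test_single_food_cell(self):
        foods, asg, tiers, scores = _scored_foods([-4])
        table = nutriscore_distribution_table(foods, scores, asg, tiers).data
        row = table.iloc[0]
        assert row["n"] == 1
        assert row["score_mean"] == pytest.approx(-4.0)
        assert (row["A_n"], row["A_pct"]) == (1, 100.0)
        assert row["omnibus_test"] == "n.a."

    def test_two_food_cell_mean_sd(self):
        foods, asg, tiers, scores = _scored_foods([0, 2])
        table = nutriscore_distribution_table(foods, scores, asg, tiers).data
        row = table.iloc[0]
        assert row["score_mean"] == pytest.approx(1.0)
        assert row["score_sd"] == pytest.approx(np.sqrt(2), rel=1e-3)
        assert (row["B_n"], row["B_pct"]) == (2, 100.0)

    def test_grade_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(-10, 30, 40).tolist()
        foods, asg, tiers, scores = _scored_foods(
            vals, groups=["NOVA1", "NOVA4"] * 20)
        table = nutriscore_distribution_table(foods, scores, asg, tiers).data
        for _, row in table.iterrows():
            total = sum(row[f"{g}_pct"] for g in "ABCDE")
            assert total == pytest.approx(100.0, abs=0.1)


class TestNutrientComparison:
    def _db(self, shift=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        foods, asg, tiers = [], [], []
        for i in range(n):
            g = "NOVA1" if i % 2 == 0 else "NOVA4"
            salt = rng.lognormal(-1, 0.3) + (shift if g == "NOVA4" else 0)
            fid = f"d{i}"
            from mednova import NutrientPanel

            foods.append(make_food(id=fid, subcategory="Vegetable",
                                   panel=NutrientPanel(salt_g=round(salt, 3))))
            asg.append(NovaAssignment(fid, g, (), "t"))
            tiers.append(TierAssignment(fid, "tMDP", "assigned", "Fruits and Vegetables"))
        return foods, asg, tiers

    def test_single_group_reports_na(self):
        foods, asg, tiers = self._db()
        asg = [NovaAssignment(a.food_id, "NOVA4", (), "t") for a in asg]
        table = nutrient_comparison_table(foods, asg, tiers).data
        salt = table[table["nutrient"] == "salt_g"]
        assert set(salt["omnibus_test"]) == {"n.a."}
        assert salt["omnibus_p"].isna().all()

    def test_undersized_group_reports_na(self):
        foods, asg, tiers = self._db(n=5)
        # make NOVA1 a single food
        asg = [NovaAssignment(a.food_id, "NOVA1" if i == 0 else "NOVA4", (), "t")
               for i, a in enumerate(asg)]
        table = nutrient_comparison_table(foods, asg, tiers).data
        salt = table[table["nutrient"] == "salt_g"]
        assert set(salt["omnibus_test"]) == {"n.a."}

    def test_shifted_salt_flagged_significant(self):
        foods, asg, tiers = self._db(shift=1.0, n=100)
        table = nutrient_comparison_table(foods, asg, tiers, alpha=0.01).data
        row = table[(table["nutrient"] == "salt_g") & (table["nova"] == "NOVA1")].iloc[0]
        assert row["pairwise_p"] < 0.01 and row["significant"]


class TestEndToEnd:
    def test_run_analysis_tables_consistent(self):
        from mednova import default_config, generate_db, run_analysis

        foods, _ = generate_db(default_config(seed=2))
        out = run_analysis(foods[:600])
        assert set(out) == {"table1", "table2", "table3", "table4", "table5",
                            "table6", "table7", "figure1"}
        t1 = out["table1"].data
        for _, row in t1.iterrows():
            assert sum(row[f"{g}_n"] for g in ("NOVA1", "NOVA2", "NOVA3", "NOVA4")) \
                == row["n"]
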