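"""Distribution tables and nonparametric group comparisons.

This module turns the per-food outputs of the classification, scoring and
tier-mapping steps into the summary tables of a food-level analysis:

* NOVA-group distributions per scope (whole database, foods eligible under
  each pyramid);
* tier x NOVA cross-tabulations, optionally split by food subcategory;
* nutrient comparisons per tier x NOVA group -- median (Q1, Q3) per
  nutrient with Kruskal-Wallis omnibus tests, Mann-Whitney pairwise tests
  against the ultra-processed (NOVA4) group, and Bonferroni adjustment;
* nutrient-profile score summaries (mean +/- SD and median (Q1, Q3)) with
  the Nutri-Score grade distribution per tier x NOVA group.

Nutrition-label data are strongly non-normal, so descriptives are medians
with interquartile ranges and all tests are rank-based. Any comparison that
involves a group with fewer than two observations is reported as not
applicable ("n.a."), never as a p-value. Quantiles use the weighted-average
(n+1)p definition (quantile type 6), the default of the common commercial
statistics packages used for this kind of analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NotApplicable
from .food_model import BrandedFood
from .nova import GROUPS, NovaAssignment
from .nutriscore import FSAmNPSResult
from .pyramid import PyramidMapping, TierAssignment

__all__ = [
    "GroupSummaryTable",
    "NUTRIENT_COLUMNS",
    "median_iqr",
    "mann_whitney_u",
    "kruskal_wallis",
    "bonferroni",
    "nova_distribution_table",
    "tier_nova_crosstab",
    "nutrient_comparison_table",
    "nutriscore_distribution_table",
    "run_analysis",
]

#: nutrients reported in the per-tier comparison tables, label order
NUTRIENT_COLUMNS = ["energy_kcal", "protein_g", "total_fat_g", "sfa_g", "sugars_g", "salt_g"]

GRADES = ("A", "B", "C", "D", "E")

#: pairwise comparisons reported against the ultra-processed group
_PAIRS = (("NOVA1", "NOVA4"), ("NOVA3", "NOVA4"))

#: exact Mann-Whitney enumeration is used up to this combined sample size
EXACT_MW_MAX_N = 12


@dataclass
class GroupSummaryTable:
    """A rendered analysis table: tidy data plus context for rendering."""

    name: str
    data: pd.DataFrame
    alpha: Optional[float] = None
    notes: str = ""

    def to_csv(self, path) -> None:
        out = self.data.copy()
        for col in out.columns:
            if col.endswith("_p") or col in ("omnibus_p",):
                out[col] = out[col].map(
                    lambda v: "n.a." if v is None or (isinstance(v, float) and math.isnan(v)) else v
                )
        out.to_csv(path, index=False)

    def to_markdown(self) -> str:
        return self.data.to_markdown(index=False)


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles with the weighted-average (n+1)p definition."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="weibull")
    return float(med), float(q1), float(q3)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two independent samples.

    The U statistic is computed from midranks. The p-value is exact (full
    enumeration of rank assignments) when the combined sample size is at
    most 12 and there are no ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction is used.

    Raises :class:`NotApplicable` when either sample has fewer than two
    observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise NotApplicable(f"group sizes {a.size}, {b.size}: need >= 2 each")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= EXACT_MW_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with the chi-square tail p-value.

    Raises :class:`NotApplicable` with fewer than two groups or any group
    smaller than two observations.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(g.size < 2 for g in arrs):
        raise NotApplicable("kruskal_wallis needs >= 2 groups of >= 2 values")
    if all(np.array_equal(g, arrs[0]) for g in arrs[1:]) and np.unique(arrs[0]).size == 1:
        # scipy rejects the all-identical degenerate case; H is 0 by definition
        return 0.0, 1.0
    res = sps.kruskal(*arrs)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------


def _nova_by_id(assignments: Sequence[NovaAssignment]) -> dict[str, str]:
    return {a.food_id: a.group for a in assignments}


def _tier_by_id(tiers: Sequence[TierAssignment]) -> dict[str, str]:
    return {t.food_id: t.tier for t in tiers if t.status == "assigned"}


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def nova_distribution_table(
    assignments: Sequence[NovaAssignment],
    tier_assignments: Optional[dict[str, Sequence[TierAssignment]]] = None,
) -> GroupSummaryTable:
    """NOVA-group counts and percentages per scope.

    Scopes are the whole table ("All") plus, for each pyramid, the subset
    of foods assigned to one of its tiers. Unclassifiable foods (no
    ingredient list) are excluded from every denominator.
    """
    nova = _nova_by_id(assignments)
    classified = {fid for fid, g in nova.items() if g in GROUPS}
    scopes: list[tuple[str, set[str]]] = [("All", classified)]
    for pyramid, tiers in (tier_assignments or {}).items():
        eligible = set(_tier_by_id(tiers))
        scopes.append((pyramid, classified & eligible))

    rows = []
    for scope_name, ids in scopes:
        n = len(ids)
        row: dict = {"scope": scope_name, "n": n}
        for g in GROUPS:
            count = sum(1 for fid in ids if nova[fid] == g)
            row[f"{g}_n"] = count
            row[f"{g}_pct"] = _pct(count, n)
        rows.append(row)
    return GroupSummaryTable(
        "nova_distribution",
        pd.DataFrame(rows),
        notes="unclassifiable foods excluded from denominators",
    )


def tier_nova_crosstab(
    foods: Sequence[BrandedFood],
    assignments: Sequence[NovaAssignment],
    tier_assignments: Sequence[TierAssignment],
    by_subcategory: bool = False,
    tier_order: Optional[Sequence[str]] = None,
) -> GroupSummaryTable:
    """Counts (row %) per NOVA group for each tier (and subcategory).

    Rows without any food are omitted; row percentages are taken within
    the tier or tier x subcategory subgroup.
    """
    nova = _nova_by_id(assignments)
    tier = _tier_by_id(tier_assignments)
    sub = {f.id: f.subcategory for f in foods}

    keys: dict[tuple, list[str]] = {}
    for fid, t in tier.items():
        if nova.get(fid) not in GROUPS:
            continue
        key = (t, sub.get(fid, "")) if by_subcategory else (t,)
        keys.setdefault(key, []).append(fid)

    order = {t: i for i, t in enumerate(tier_order)} if tier_order else {}
    rows = []
    for key in sorted(keys, key=lambda k: (order.get(k[0], len(order)), k)):
        ids = keys[key]
        n = len(ids)
        row: dict = {"tier": key[0]}
        if by_subcategory:
            row["subcategory"] = key[1]
        row["n"] = n
        for g in GROUPS:
            count = sum(1 for fid in ids if nova[fid] == g)
            row[f"{g}_n"] = count
            row[f"{g}_pct"] = _pct(count, n)
        rows.append(row)
    name = "tier_subcategory_nova_crosstab" if by_subcategory else "tier_nova_crosstab"
    return GroupSummaryTable(name, pd.DataFrame(rows), notes="empty rows omitted")


def _group_values(
    subset: pd.DataFrame, column: str
) -> dict[str, np.ndarray]:
    """Non-missing values of ``column`` per NOVA group, groups with data only."""
    out = {}
    for g in GROUPS:
        vals = subset.loc[subset["nova"] == g, column].dropna().to_numpy()
        if vals.size:
            out[g] = vals
    return out


def _omnibus(groups: dict[str, np.ndarray]) -> tuple[Optional[float], str]:
    """Omnibus p across NOVA groups, or (None, "n.a.") when not testable.

    Not applicable when fewer than two groups carry data or any group has
    fewer than two observations.
    """
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        return None, "n.a."
    samples = list(groups.values())
    if len(samples) == 2:
        _, p = mann_whitney_u(samples[0], samples[1])
        return p, "mannwhitney"
    _, p = kruskal_wallis(samples)
    return p, "kruskal"


def _pairwise_vs_nova4(
    groups: dict[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted Mann-Whitney p per testable pair vs NOVA4."""
    testable = [
        pair
        for pair in _PAIRS
        if pair[0] in groups
        and pair[1] in groups
        and groups[pair[0]].size >= 2
        and groups[pair[1]].size >= 2
    ]
    raw = {}
    for pair in testable:
        _, p = mann_whitney_u(groups[pair[0]], groups[pair[1]])
        raw[pair] = p
    m = len(testable)
    return {pair: bonferroni(p, m) for pair, p in raw.items()}


def _build_frame(
    foods: Sequence[BrandedFood],
    assignments: Sequence[NovaAssignment],
    tier_assignments: Sequence[TierAssignment],
    scores: Optional[Sequence[FSAmNPSResult]] = None,
) -> pd.DataFrame:
    nova = _nova_by_id(assignments)
    tier = _tier_by_id(tier_assignments)
    score_by_id = {s.food_id: s for s in scores} if scores is not None else {}
    rows = []
    for f in foods:
        g = nova.get(f.id)
        t = tier.get(f.id)
        if g not in GROUPS or t is None:
            continue
        row = {
            "food_id": f.id,
            "tier": t,
            "subcategory": f.subcategory,
            "nova": g,
        }
        for nutrient in NUTRIENT_COLUMNS:
            v = f.panel.get(nutrient)
            row[nutrient] = np.nan if v is None else v
        if scores is not None:
            s = score_by_id.get(f.id)
            if s is None or s.status != "scored":
                continue
            row["score"] = s.score
            row["grade"] = s.grade
        rows.append(row)
    return pd.DataFrame(rows)


def nutrient_comparison_table(
    foods: Sequence[BrandedFood],
    assignments: Sequence[NovaAssignment],
    tier_assignments: Sequence[TierAssignment],
    alpha: float = 0.01,
    tier_order: Optional[Sequence[str]] = None,
) -> GroupSummaryTable:
    """Median (Q1, Q3) per nutrient, tier and NOVA group, with tests.

    One row per tier x NOVA group x nutrient. ``omnibus_p`` is shared by
    the rows of one tier x nutrient; ``pairwise_p`` is the
    Bonferroni-adjusted Mann-Whitney p of that row's group against NOVA4;
    ``significant`` flags adjusted p < alpha. Untestable comparisons carry
    ``None``/NaN and test label "n.a.".
    """
    df = _build_frame(foods, assignments, tier_assignments)
    order = {t: i for i, t in enumerate(tier_order)} if tier_order else {}
    rows = []
    for t in sorted(df["tier"].unique(), key=lambda t: (order.get(t, len(order)), t)):
        subset = df[df["tier"] == t]
        for nutrient in NUTRIENT_COLUMNS:
            groups = _group_values(subset, nutrient)
            omnibus_p, test = _omnibus(groups)
            adj = _pairwise_vs_nova4(groups)
            for g in GROUPS:
                if g not in groups:
                    continue
                vals = groups[g]
                med, q1, q3 = median_iqr(vals)
                pair_p = adj.get((g, "NOVA4"))
                rows.append(
                    {
                        "tier": t,
                        "nova": g,
                        "nutrient": nutrient,
                        "n": int(vals.size),
                        "median": med,
                        "q1": q1,
                        "q3": q3,
                        "omnibus_test": test,
                        "omnibus_p": omnibus_p,
                        "pairwise_p": pair_p,
                        "significant": bool(pair_p is not None and pair_p < alpha),
                    }
                )
    return GroupSummaryTable(
        "nutrient_comparison",
        pd.DataFrame(rows),
        alpha=alpha,
        notes="pairwise tests are NOVA1/NOVA3 vs NOVA4, Bonferroni-adjusted per tier x nutrient",
    )


def nutriscore_distribution_table(
    foods: Sequence[BrandedFood],
    scores: Sequence[FSAmNPSResult],
    assignments: Sequence[NovaAssignment],
    tier_assignments: Sequence[TierAssignment],
    alpha: float = 0.01,
    tier_order: Optional[Sequence[str]] = None,
) -> GroupSummaryTable:
    """FSAm-NPS summaries and Nutri-Score grade distribution per tier x NOVA.

    One row per tier x NOVA group (scored foods only): mean +/- SD and
    median (Q1, Q3) of the score, grade counts A-E with row percentages,
    plus the same omnibus/pairwise testing scheme as the nutrient table.
    """
    df = _build_frame(foods, assignments, tier_assignments, scores=scores)
    order = {t: i for i, t in enumerate(tier_order)} if tier_order else {}
    rows = []
    if df.empty:
        return GroupSummaryTable("nutriscore_distribution", pd.DataFrame(), alpha=alpha)
    for t in sorted(df["tier"].unique(), key=lambda t: (order.get(t, len(order)), t)):
        subset = df[df["tier"] == t]
        groups = _group_values(subset, "score")
        omnibus_p, test = _omnibus(groups)
        adj = _pairwise_vs_nova4(groups)
        for g in GROUPS:
            if g not in groups:
                continue
            vals = groups[g]
            sub_g = subset[subset["nova"] == g]
            med, q1, q3 = median_iqr(vals)
            pair_p = adj.get((g, "NOVA4"))
            row = {
                "tier": t,
                "nova": g,
                "n": int(vals.size),
                "score_mean": float(np.mean(vals)),
                "score_sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                "score_median": med,
                "score_q1": q1,
                "score_q3": q3,
                "omnibus_test": test,
                "omnibus_p": omnibus_p,
                "pairwise_p": pair_p,
                "significant": bool(pair_p is not None and pair_p < alpha),
            }
            for grade_letter in GRADES:
                count = int((sub_g["grade"] == grade_letter).sum())
                row[f"{grade_letter}_n"] = count
                row[f"{grade_letter}_pct"] = _pct(count, len(sub_g))
            rows.append(row)
    return GroupSummaryTable(
        "nutriscore_distribution",
        pd.DataFrame(rows),
        alpha=alpha,
        notes="scored foods only; excluded foods dropped",
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


def run_analysis(
    foods: Sequence[BrandedFood],
    lexicon=None,
    tables=None,
    mappings: Optional[dict[str, PyramidMapping]] = None,
    alpha: float = 0.01,
) -> dict[str, GroupSummaryTable]:
    """Run the full pipeline and produce every summary table.

    Returns a dict keyed ``table1`` (scope distributions), ``table2`` /
    ``table3`` (tier x subcategory crosstabs per pyramid), ``table4`` /
    ``table5`` (nutrient comparisons), ``table6`` / ``table7``
    (score/grade distributions) and ``figure1`` (tier-level NOVA
    percentages for both pyramids), mirroring the layout of a food-level
    branded-database analysis.
    """
    from .nova import classify_all, default_lexicon
    from .nutriscore import default_score_tables, score_all
    from .pyramid import assign_all, default_mappings

    lexicon = lexicon or default_lexicon()
    tables = tables or default_score_tables()
    mappings = mappings or default_mappings()

    assignments = classify_all(foods, lexicon)
    scores = score_all(foods, tables)
    tiers = {name: assign_all(foods, m) for name, m in mappings.items()}

    out: dict[str, GroupSummaryTable] = {}
    out["table1"] = nova_distribution_table(assignments, tiers)

    fig_rows = []
    for idx, (name, mapping) in enumerate(mappings.items()):
        crosstab = tier_nova_crosstab(
            foods, assignments, tiers[name], by_subcategory=True, tier_order=mapping.tiers
        )
        out[f"table{2 + idx}"] = crosstab
        out[f"table{4 + idx}"] = nutrient_comparison_table(
            foods, assignments, tiers[name], alpha=alpha, tier_order=mapping.tiers
        )
        out[f"table{6 + idx}"] = nutriscore_distribution_table(
            foods, scores, assignments, tiers[name], alpha=alpha, tier_order=mapping.tiers
        )
        tier_level = tier_nova_crosstab(
            foods, assignments, tiers[name], by_subcategory=False, tier_order=mapping.tiers
        ).data
        tier_level.insert(0, "pyramid", name)
        fig_rows.append(tier_level)
    out["figure1"] = GroupSummaryTable(
        "tier_nova_percentages",
        pd.concat(fig_rows, ignore_index=True) if fig_rows else pd.DataFrame(),
        notes="tier-level NOVA percentages per pyramid",
    )
    return out
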