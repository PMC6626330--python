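"""Decompose residual-associated spending to individual diagnosis codes.

Three steps, applied within one disease category (a 3-digit code-prefix
family such as 401xx essential hypertension or 585xx chronic kidney
disease): (1) attribute each claim's cost to its principal diagnosis
code; (2) sort the disease cohort by residual from high to low and chunk
it into fixed-size groups; (3) tabulate, per (group, code), the number of
patients and the group-mean per-member per-month cost.  The table makes
visible whether spending variation sits *within* a code (the same
diagnosis costing far more at the high-residual end) or comes from a
shifting *mixture* of codes (e.g. more end-stage disease at the top).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def category_codes(claims: pd.DataFrame, prefix: str) -> list[str]:
    """Distinct principal codes matching a 3-digit prefix family."""
    codes = claims["principal_dx"].astype(str)
    return sorted(codes[codes.str.startswith(prefix)].unique())


def attribute_claim_costs(claims: pd.DataFrame,
                          months: pd.Series,
                          category: str | set[str],
                          year: int | None = None) -> pd.DataFrame:
    """Per-member, per-code PMPM for claims inside one disease category.

    ``category`` is a code prefix (e.g. '401') or an explicit code set;
    ``months`` maps member_id -> months enrolled and defines the cohort —
    claims of members absent from it, or outside the category, contribute
    nothing.  Returns columns (member_id, principal_dx, pmpm).
    """
    df = claims if year is None else claims[claims["year"] == year]
    codes = df["principal_dx"].astype(str)
    if isinstance(category, str):
        if not category:
            raise ValueError("empty category prefix")
        in_cat = codes.str.startswith(category)
    else:
        if not category:
            raise ValueError("empty category code set")
        in_cat = codes.isin(set(category))
    sub = df[in_cat & df["member_id"].isin(months.index)]
    totals = (sub.groupby(["member_id", "principal_dx"])["paid_amount"]
              .sum().reset_index())
    totals["pmpm"] = (totals["paid_amount"]
                      / totals["member_id"].map(months).to_numpy(float))
    return totals[["member_id", "principal_dx", "pmpm"]]


def group_by_residual(residuals: pd.Series,
                      group_size: int = 5000) -> pd.Series:
    """Chunk members into consecutive groups of ``group_size`` by residual.

    Group 0 holds the highest residuals; the last group may be smaller.
    Ties are broken by member id ascending for determinism.
    """
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    df = residuals.rename("residual").rename_axis("member_id").reset_index()
    df = df.sort_values(["residual", "member_id"],
                        ascending=[False, True], kind="mergesort")
    df["group_index"] = np.arange(len(df)) // group_size
    return df.set_index("member_id")["group_index"]


def breakdown_table(groups: pd.Series,
                    per_code_costs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient counts and mean per-code PMPM per residual group.

    Returns ``(cells, group_totals)``: ``cells`` has one row per
    (group_index, principal_dx) with the number of patients having any
    cost on that code and the group-mean PMPM for the code (averaged over
    ALL group members, zero for members without the code, so per-group
    code means sum exactly to the group's category total);
    ``group_totals`` has per-group n and mean category PMPM.
    """
    group_sizes = groups.value_counts().sort_index()
    costs = per_code_costs.copy()
    costs["group_index"] = costs["member_id"].map(groups)
    costs = costs.dropna(subset=["group_index"])
    costs["group_index"] = costs["group_index"].astype(int)

    cells = (costs.groupby(["group_index", "principal_dx"])
             .agg(n_patients=("member_id", "nunique"),
                  total_pmpm=("pmpm", "sum"))
             .reset_index())
    cells["mean_pmpm"] = (cells["total_pmpm"]
                          / cells["group_index"].map(group_sizes))
    cells = cells.drop(columns="total_pmpm")

    member_cat = costs.groupby(["group_index", "member_id"])["pmpm"].sum()
    group_totals = (member_cat.groupby("group_index").sum()
                    / group_sizes).rename("mean_category_pmpm").to_frame()
    group_totals["n_members"] = group_sizes
    group_totals = group_totals.reindex(group_sizes.index).fillna(
        {"mean_category_pmpm": 0.0})
    return cells, group_totals.reset_index().rename(
        columns={"index": "group_index"})
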