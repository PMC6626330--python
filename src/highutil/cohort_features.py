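"""Cohort construction and design matrix for expenditure risk adjustment.

Applies the study inclusion rules (adults 18-60, not pregnant, nonzero
annual expenditure), normalizes spending to per-member per-month (PMPM)
dollars, log10-transforms it, groups diagnosis codes into clinical
categories via a two-column mapping table, and builds the one-hot design
matrix (intercept + condition indicators + demographics + county + plan)
whose response is log10 PMPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

AGE_MIN, AGE_MAX = 18, 60

# Synthetic Charlson-style weights over the generator's condition
# categories; the weight map is configurable, so real CCS-based weights can
# be supplied for real data.
DEFAULT_CHARLSON_WEIGHTS: dict[str, float] = {
    "CKD": 2.0, "DIAB": 1.0, "COPD": 1.0, "CANCER": 2.0,
    "CARDIAC": 1.0, "HTN": 1.0,
}


def compute_pmpm(total_expenditure: float, months_enrolled: int) -> float:
    """Per-member per-month expenditure: total paid / months enrolled."""
    if months_enrolled <= 0:
        raise ValueError("months_enrolled must be >= 1")
    return total_expenditure / months_enrolled


def log_transform(pmpm: float | np.ndarray) -> float | np.ndarray:
    """Base-10 log of PMPM; requires strictly positive spending."""
    if np.any(np.asarray(pmpm) <= 0):
        raise ValueError("log transform requires pmpm > 0; "
                         "zero-expenditure members must be excluded upstream")
    return np.log10(pmpm)


def apply_inclusion(members: pd.DataFrame, claims: pd.DataFrame,
                    year: int) -> set[str]:
    """Members aged 18-60, not pregnant, with nonzero paid amounts in `year`."""
    my = members[members["year"] == year]
    if my.empty:
        raise ValueError(f"year {year} absent from member table")
    totals = (claims[claims["year"] == year]
              .groupby("member_id")["paid_amount"].sum())
    eligible = my[
        my["age"].between(AGE_MIN, AGE_MAX) & ~my["pregnant"].astype(bool)
    ]["member_id"]
    positive = set(totals[totals > 0].index)
    return set(eligible) & positive


def group_diagnoses(claims: pd.DataFrame,
                    mapping: pd.DataFrame | dict[str, str]) -> pd.Series:
    """Per-member set of condition categories from principal diagnoses.

    Unmapped codes are routed to the UNCLASSIFIED catch-all and logged,
    so no claim is silently dropped.
    """
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping["code"].astype(str),
                           mapping["category"].astype(str)))
    codes = claims["principal_dx"].astype(str)
    cats = codes.map(mapping)
    n_unmapped = int(cats.isna().sum())
    if n_unmapped:
        logger.warning("%d claims carry unmapped diagnosis codes; "
                       "routed to %s", n_unmapped, UNCLASSIFIED)
        cats = cats.fillna(UNCLASSIFIED)
    return cats.groupby(claims["member_id"]).agg(set)


def charlson_index(categories: set[str],
                   weights: dict[str, float] | None = None) -> float:
    """Weighted comorbidity score: sum of weights over distinct categories.

    Categories without a weight contribute 0.
    """
    if weights is None:
        weights = DEFAULT_CHARLSON_WEIGHTS
    return float(sum(weights.get(c, 0.0) for c in set(categories)))


def build_cohort(members: pd.DataFrame, claims: pd.DataFrame,
                 mapping: pd.DataFrame | dict[str, str],
                 year: int) -> pd.DataFrame:
    """One row per included member with PMPM, log10 PMPM and covariates.

    Condition categories are derived from the year's claims through the
    mapping table (not from any generator-side column), mirroring how a
    claims warehouse would be processed.
    """
    included = apply_inclusion(members, claims, year)
    my = members[(members["year"] == year)
                 & members["member_id"].isin(included)].copy()
    yc = claims[claims["year"] == year]
    yc = yc[yc["member_id"].isin(included)]
    totals = yc.groupby("member_id")["paid_amount"].sum()
    cats = group_diagnoses(yc, mapping)

    my = my.set_index("member_id")
    my["total_expenditure"] = totals
    my["pmpm"] = my["total_expenditure"] / my["months_enrolled"]
    my["log10_pmpm"] = np.log10(my["pmpm"])
    my["categories"] = cats.reindex(my.index).apply(
        lambda s: s if isinstance(s, set) else set())
    return my.reset_index().sort_values("member_id").reset_index(drop=True)


@dataclass
class DesignMatrix:
    """Response vector and one-hot covariate matrix for the risk models."""

    y: np.ndarray                 # log10 PMPM
    X: pd.DataFrame               # intercept + one-hot/numeric covariates
    member_ids: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


CATEGORICAL_COVARIATES = ["sex", "race", "county", "plan"]


def build_design_matrix(cohort: pd.DataFrame,
                        categoricals: list[str] | None = None) -> DesignMatrix:
    """Design matrix: intercept + condition indicators + demographics.

    Categorical covariates are one-hot encoded with the first (sorted)
    level dropped as the reference; condition categories are multi-label
    binary indicators and are all kept.  Zero-variance columns (e.g. a
    condition present in every row, exactly collinear with the intercept)
    are dropped and reported.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if categoricals is None:
        categoricals = CATEGORICAL_COVARIATES
    cohort = cohort.sort_values("member_id")

    blocks = [pd.DataFrame({"intercept": np.ones(len(cohort))},
                           index=cohort.index)]
    all_cats = sorted(set().union(*cohort["categories"]))
    if all_cats:
        cat_block = pd.DataFrame(
            {f"cond_{c}": cohort["categories"].apply(lambda s, c=c: float(c in s))
             for c in all_cats}, index=cohort.index)
        blocks.append(cat_block)
    num = pd.DataFrame({"age": cohort["age"].astype(float),
                        "disabled": cohort["disabled"].astype(float)},
                       index=cohort.index)
    blocks.append(num)
    for col in categoricals:
        dummies = pd.get_dummies(cohort[col].astype(str), prefix=col,
                                 drop_first=True, dtype=float)
        blocks.append(dummies)
    X = pd.concat(blocks, axis=1)

    dropped = [c for c in X.columns
               if c != "intercept" and X[c].nunique() <= 1]
    if dropped:
        logger.warning("dropping zero-variance design columns: %s", dropped)
        X = X.drop(columns=dropped)

    y = cohort["log10_pmpm"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response; cohort rules violated")
    return DesignMatrix(y=y, X=X,
                        member_ids=cohort["member_id"].to_numpy(),
                        dropped_columns=dropped)
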