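"""Setting-stratified risk adjustment and preventable-event association.

The overall model is re-run on cohorts restricted to members with nonzero
spending in one service setting (inpatient hospital or emergency
department), with the dependent variable rebuilt from that setting's
claims only; independent variables are unchanged.  The stratified
residuals are then compared against potentially-preventable-event (PPE)
measures — preventable readmission (PPR) and preventable ED visit (PPV)
counts and expenditures — for the index year and the following year:
group-mean contrasts with two-sided Mann-Whitney U tests, and Pearson
correlations between residuals and log10 PMPM PPE expenditures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_features import DesignMatrix, build_cohort, build_design_matrix
from .risk_models import LinearFit, fit_linear
from .tail_detection import flag_high_utilizers

STRATA = ("inpatient", "emergency")

PPE_MEASURES = ["ppr_count", "ppr_expenditure", "ppv_count", "ppv_expenditure"]


def stratify_cohort(claims: pd.DataFrame, setting: str,
                    year: int, months: pd.Series) -> pd.Series:
    """Setting-specific PMPM for members with nonzero spend in the setting.

    Returns a Series indexed by member_id; membership in the stratum is
    exactly the members present in the index.
    """
    if setting not in STRATA:
        raise ValueError(f"unknown setting {setting!r}; expected one of {STRATA}")
    sub = claims[(claims["year"] == year) & (claims["setting"] == setting)]
    totals = sub.groupby("member_id")["paid_amount"].sum()
    totals = totals[(totals > 0) & totals.index.isin(months.index)]
    pmpm = totals / totals.index.map(months).to_numpy(float)
    return pmpm.rename("setting_pmpm")


@dataclass
class StratifiedFit:
    setting: str
    year: int
    cohort: pd.DataFrame
    fit: LinearFit
    flags: pd.DataFrame
    flagged_fraction: float


def fit_stratified(members: pd.DataFrame, claims: pd.DataFrame,
                   mapping, setting: str, year: int,
                   delta: float = 0.1, min_frac: float = 0.01,
                   max_frac: float = 0.07) -> StratifiedFit:
    """Risk-adjust log10 setting-specific PMPM and flag the high tail.

    The cohort is the year's included members restricted to nonzero spend
    in the setting; covariates are identical to the overall model.
    """
    cohort = build_cohort(members, claims, mapping, year)
    months = cohort.set_index("member_id")["months_enrolled"]
    setting_pmpm = stratify_cohort(claims, setting, year, months)
    sub = cohort[cohort["member_id"].isin(setting_pmpm.index)].copy()
    if len(sub) < 50:
        raise ValueError(f"{setting} stratum too small ({len(sub)} members)")
    sub["pmpm"] = sub["member_id"].map(setting_pmpm)
    sub["log10_pmpm"] = np.log10(sub["pmpm"])
    design = build_design_matrix(sub)
    fit = fit_linear(design)
    flags = flag_high_utilizers(fit.residuals, mode="threshold", delta=delta,
                                min_frac=min_frac, max_frac=max_frac)
    return StratifiedFit(setting=setting, year=year, cohort=sub, fit=fit,
                         flags=flags,
                         flagged_fraction=float(flags["high_utilizer"].mean()))


def compare_ppe(flags: pd.DataFrame, ppe: pd.DataFrame,
                index_year: int, next_year: int | None = None) -> pd.DataFrame:
    """Group-mean PPE contrasts with Mann-Whitney U tests.

    One row per (measure, year offset): mean for the flagged high-residual
    group, mean for others, and the two-sided Mann-Whitney U statistic and
    p-value.  Next-year rows condition on presence in the next year's PPE
    table (pairwise deletion); they are omitted when ``next_year`` is None.
    """
    flagged = set(flags.loc[flags["high_utilizer"], "member_id"])
    cohort_ids = set(flags["member_id"])
    rows = []
    year_blocks = [("index", index_year)]
    if next_year is not None:
        year_blocks.append(("next", next_year))
    for label, yr in year_blocks:
        yp = ppe[(ppe["year"] == yr) & ppe["member_id"].isin(cohort_ids)]
        grp_high = yp[yp["member_id"].isin(flagged)]
        grp_other = yp[~yp["member_id"].isin(flagged)]
        if grp_high.empty or grp_other.empty:
            raise ValueError(f"empty comparison group for year {yr}")
        for measure in PPE_MEASURES:
            a = grp_high[measure].to_numpy(float)
            b = grp_other[measure].to_numpy(float)
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({
                "measure": measure, "year": yr, "offset": label,
                "mean_high": a.mean(), "mean_other": b.mean(),
                "mannwhitney_u": float(u), "p_value": float(p),
                "n_high": len(a), "n_other": len(b),
            })
    return pd.DataFrame(rows)


def ppe_residual_correlation(residuals: pd.Series, ppe: pd.DataFrame,
                             months: pd.Series, measure: str,
                             year: int) -> tuple[float, int]:
    """Pearson r between residuals and log10 PMPM PPE expenditures.

    Restricted to members with positive PPE expenditure in the target
    year (the log is undefined otherwise).  ``measure`` is
    'ppr_expenditure' or 'ppv_expenditure'; ``months`` maps member_id ->
    months enrolled for the PMPM normalization.  Returns (r, n).
    """
    yp = ppe[ppe["year"] == year].set_index("member_id")
    exp = yp[measure]
    exp = exp[exp > 0]
    common = residuals.index.intersection(exp.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 members with positive PPE spend")
    pmpm = exp.loc[common] / common.map(months).to_numpy(float)
    r = float(np.corrcoef(residuals.loc[common].to_numpy(float),
                          np.log10(pmpm.to_numpy(float)))[0, 1])
    return r, len(common)
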