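"""Year-to-year persistence of risk-adjusted residuals.

Two-step procedure: (1) convert each year's residuals to average-rank
percentiles; (2) correlate the percentiles of members present in both
years of a pair (Pearson).  Also reports the mean next-year percentile of
an index-year flagged group versus everyone else — persistent high
utilizers keep ranking high the following year.

Signed residuals are ranked by default: the downstream follow-up
statistics (a flagged group that averages ~75th percentile next year)
only make sense for a signed ranking, where over- and under-utilizers
occupy opposite tails.  Ranking absolute residuals is available behind
``use_absolute`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def rank_percentiles(residuals: pd.Series,
                     use_absolute: bool = False) -> pd.Series:
    """Average-rank percentile in (0, 1]; ties get their mean rank."""
    if len(residuals) == 0:
        raise ValueError("empty residual table")
    vals = residuals.to_numpy(float)
    if use_absolute:
        vals = np.abs(vals)
    ranks = stats.rankdata(vals, method="average")
    return pd.Series(ranks / len(vals), index=residuals.index,
                     name="rank_percentile")


@dataclass
class YearPairCorrelation:
    year_a: int
    year_b: int
    pearson_r: float
    n_members_in_both: int


def year_pair_correlation(pct_a: pd.Series, pct_b: pd.Series,
                          year_a: int = 0, year_b: int = 0) -> YearPairCorrelation:
    """Pearson r of rank percentiles over members present in both years."""
    common = pct_a.index.intersection(pct_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 members present in both years")
    a = pct_a.loc[common].to_numpy(float)
    b = pct_b.loc[common].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a percentile vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return YearPairCorrelation(year_a=year_a, year_b=year_b,
                               pearson_r=r, n_members_in_both=len(common))


def correlation_matrix(residuals_by_year: dict[int, pd.Series],
                       use_absolute: bool = False) -> pd.DataFrame:
    """Upper-triangular year-pair correlation table of rank percentiles."""
    years = sorted(residuals_by_year)
    pct = {y: rank_percentiles(residuals_by_year[y], use_absolute)
           for y in years}
    out = pd.DataFrame(index=years[:-1], columns=years[1:], dtype=float)
    for i, ya in enumerate(years):
        for yb in years[i + 1:]:
            out.loc[ya, yb] = year_pair_correlation(pct[ya], pct[yb],
                                                    ya, yb).pearson_r
    return out


def mean_followup_percentile(index_flags: pd.DataFrame | set,
                             next_percentiles: pd.Series) -> tuple[float, float]:
    """Mean next-year percentile of the index-year flagged group vs others.

    Members absent from the later year are dropped pairwise.
    """
    if isinstance(index_flags, pd.DataFrame):
        flagged = set(index_flags.loc[index_flags["high_utilizer"],
                                      "member_id"])
    else:
        flagged = set(index_flags)
    present = next_percentiles.index
    flagged_present = [m for m in present if m in flagged]
    if not flagged_present:
        raise ValueError("no flagged member persists to the later year")
    other_present = present.difference(flagged_present)
    return (float(next_percentiles.loc[flagged_present].mean()),
            float(next_percentiles.loc[other_present].mean()))
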