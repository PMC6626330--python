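"""High-utilizer identification from the residual distribution's right tail.

If the measured risk factors explained all systematic variation, the
standardized residuals would be normal; an abnormally long right tail
marks members whose spending the model cannot account for.  The empirical
threshold is the point from which every higher order statistic exceeds its
theoretical normal quantile by more than ``delta`` — i.e. the deviation is
consistent from there rightward — with the implied flagged fraction
clipped into a configured range (default 1%-7%, the range the flagged
share is expected to occupy).  A fixed top-k cutoff (e.g. top 5%) is the
alternative flagging mode used for model comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_features import charlson_index
from .risk_models import qq_data

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.1
DEFAULT_MIN_FRAC = 0.01
DEFAULT_MAX_FRAC = 0.07


@dataclass
class TailThreshold:
    """Detected standardized-residual threshold and its implied fraction."""

    threshold: float          # standardized-residual scale
    fraction: float           # flagged share of the population
    fallback: bool            # True when no consistent deviation was found


def detect_tail_threshold(qq_pairs: pd.DataFrame,
                          delta: float = DEFAULT_DELTA,
                          min_frac: float = DEFAULT_MIN_FRAC,
                          max_frac: float = DEFAULT_MAX_FRAC) -> TailThreshold:
    """Find where the right tail consistently exceeds normal quantiles.

    Returns the smallest standardized residual t such that every order
    statistic above t deviates from its theoretical quantile by more than
    ``delta``; the implied flagged fraction is clipped into
    ``[min_frac, max_frac]``.  Extreme order statistics whose asymptotic
    quantile standard error exceeds delta/4 are excluded from the
    consistency scan — their sampling noise is comparable to the deviation
    being tested, so they can neither confirm nor break consistency (they
    are still flagged once above the threshold).  If no point deviates
    consistently the ``max_frac`` quantile is returned with a warning.
    """
    if not (0 < min_frac < max_frac < 0.5):
        raise ValueError("require 0 < min_frac < max_frac < 0.5")
    obs = qq_pairs["observed"].to_numpy(float)
    theo = qq_pairs["theoretical"].to_numpy(float)
    n = len(obs)
    dev = obs - theo

    pp = (np.arange(1, n + 1) - 0.5) / n
    with np.errstate(over="ignore"):
        quantile_se = (np.sqrt(pp * (1.0 - pp) / n)
                       / np.maximum(stats.norm.pdf(theo), 1e-300))
    informative = quantile_se <= delta / 4.0
    exceeds = dev > delta
    # longest suffix in which every informative point exceeds delta
    ok = exceeds | ~informative
    if not ok[-1]:
        start = n
    else:
        run = np.where(~ok)[0]
        start = (run[-1] + 1) if len(run) else 0
    fallback = start >= n or not informative[start:].any()
    if fallback:
        logger.warning("no consistent right-tail deviation beyond delta=%g; "
                       "falling back to the %.0f%% quantile",
                       delta, 100 * max_frac)
        fraction = max_frac
    else:
        fraction = (n - start) / n

    fraction = min(max(fraction, min_frac), max_frac)
    k = max(int(math.floor(fraction * n)), 1)
    # threshold sits just below the k-th largest standardized residual
    threshold = obs[n - k] - 1e-12 if k <= n else obs[0]
    return TailThreshold(threshold=float(threshold),
                         fraction=k / n, fallback=fallback)


def top_k_count(n_population: int, fraction: float) -> int:
    """Size of the top-`fraction` group: floor(fraction * N)."""
    if n_population <= 0:
        raise ValueError("population must be positive")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    return int(math.floor(fraction * n_population))


def rank_percentile(residuals: pd.Series) -> pd.Series:
    """Average-rank percentile in (0, 1], ties share their mean rank."""
    ranks = stats.rankdata(residuals.to_numpy(float), method="average")
    return pd.Series(ranks / len(residuals), index=residuals.index,
                     name="rank_percentile")


def flag_high_utilizers(residuals: pd.Series,
                        mode: str = "threshold",
                        fraction: float = 0.05,
                        delta: float = DEFAULT_DELTA,
                        min_frac: float = DEFAULT_MIN_FRAC,
                        max_frac: float = DEFAULT_MAX_FRAC) -> pd.DataFrame:
    """Flag the high-residual population for one year.

    ``mode='threshold'`` detects the consistent-deviation point on the
    standardized Q-Q curve and flags members above it; ``mode='top'``
    flags the floor(fraction * N) largest residuals.  Ties are broken by
    (residual descending, member_id ascending) so both modes are
    deterministic and flag exactly k members.
    """
    res = residuals.rename("residual").rename_axis("member_id").reset_index()
    n = len(res)
    if mode == "top":
        if not (0 < fraction < 0.5):
            raise ValueError("fraction must be in (0, 0.5)")
        k = top_k_count(n, fraction)
    elif mode == "threshold":
        tail = detect_tail_threshold(qq_data(res["residual"].to_numpy()),
                                     delta=delta, min_frac=min_frac,
                                     max_frac=max_frac)
        k = max(int(round(tail.fraction * n)), 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    order = res.sort_values(["residual", "member_id"],
                            ascending=[False, True], kind="mergesort")
    flagged_ids = set(order["member_id"].iloc[:k])
    res["rank_percentile"] = rank_percentile(
        res.set_index("member_id")["residual"]).to_numpy()
    res["high_utilizer"] = res["member_id"].isin(flagged_ids)
    return res


def overlap(flags_a: pd.DataFrame | set,
            flags_b: pd.DataFrame | set) -> tuple[int, float]:
    """Intersection count and percent of A, rounded to one decimal."""
    set_a = _flag_set(flags_a)
    set_b = _flag_set(flags_b)
    if not set_a:
        raise ValueError("empty flag set A")
    inter = len(set_a & set_b)
    return inter, round(100.0 * inter / len(set_a), 1)


def _flag_set(flags) -> set:
    if isinstance(flags, pd.DataFrame):
        return set(flags.loc[flags["high_utilizer"], "member_id"])
    return set(flags)


def characterize(cohort: pd.DataFrame, flags: pd.DataFrame,
                 claims: pd.DataFrame | None = None,
                 charlson_weights: dict[str, float] | None = None,
                 mental_categories: set[str] = frozenset({"MOOD", "PSYCH"}),
                 substance_categories: set[str] = frozenset({"SUBST"}),
                 ) -> pd.DataFrame:
    """Compare flagged high utilizers with other patients.

    Returns a characteristics table (rows = measures, columns = the two
    groups) covering demographics, comorbidity burden (Charlson-style
    score, mental illness and substance-use shares) and, when claims are
    supplied, utilization by service setting.
    """
    flagged = _flag_set(flags)
    df = cohort.copy()
    df["group"] = np.where(df["member_id"].isin(flagged),
                           "high_utilizers", "others")
    groups = df.groupby("group")
    if df["group"].nunique() < 2:
        logger.warning("single group present; comparison columns will be NA")

    rows: dict[str, pd.Series] = {}
    rows["n"] = groups.size().astype(float)
    rows["mean_age"] = groups["age"].mean()
    rows["pct_female"] = groups["sex"].apply(lambda s: 100.0 * (s == "F").mean())
    for race in sorted(df["race"].unique()):
        rows[f"pct_race_{race}"] = groups["race"].apply(
            lambda s, r=race: 100.0 * (s == r).mean())
    rows["pct_disabled"] = groups["disabled"].apply(
        lambda s: 100.0 * s.astype(bool).mean())
    rows["mean_charlson"] = groups["categories"].apply(
        lambda s: float(np.mean([charlson_index(c, charlson_weights)
                                 for c in s])))
    rows["pct_mental_illness"] = groups["categories"].apply(
        lambda s: 100.0 * s.apply(lambda c: bool(c & set(mental_categories))).mean())
    rows["pct_substance_use"] = groups["categories"].apply(
        lambda s: 100.0 * s.apply(lambda c: bool(c & set(substance_categories))).mean())
    rows["mean_total_expenditure"] = groups["total_expenditure"].mean()

    if claims is not None:
        yc = claims.merge(df[["member_id", "group"]], on="member_id")
        setting_map = {"professional": "professional",
                       "inpatient": "institutional",
                       "other": "institutional",
                       "pharmacy": "pharmacy"}
        for setting, label in [("professional", "professional"),
                               ("pharmacy", "pharmacy")]:
            spend = (yc[yc["setting"] == setting]
                     .groupby("group")["paid_amount"].sum())
            rows[f"mean_{label}_expenditure"] = spend / rows["n"]
        inst = (yc[yc["setting"].isin(["inpatient", "other"])]
                .groupby("group")["paid_amount"].sum())
        rows["mean_institutional_expenditure"] = inst / rows["n"]
        for setting, label in [("emergency", "ed_visits"),
                               ("inpatient", "inpatient_visits")]:
            visits = (yc[yc["setting"] == setting]
                      .groupby("group").size().astype(float))
            rows[f"mean_{label}"] = visits / rows["n"]

    table = pd.DataFrame(rows).T
    for col in ["high_utilizers", "others"]:
        if col not in table.columns:
            table[col] = np.nan
    return table[["high_utilizers", "others"]]
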