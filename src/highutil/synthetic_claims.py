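"""Synthetic multi-year Medicaid-style claims generator.

Emulates the statistical structure that residual-based high-utilizer
analysis assumes: per-member per-month (PMPM) expenditures that are
log10-normal around a linear function of demographic and condition
covariates, a small planted subpopulation with persistent excess
utilization, member-level persistent frailty driving year-to-year
correlation of unexplained spending, diagnosis-code mixtures that shift
with excess utilization, and preventable-event (PPR/PPV) counts coupled
to the member's unexplained spending propensity.

The generating model for member i in year t is

    log10 PMPM_it = beta . x_it + u_it + v_it + w_it

where ``u`` is the planted latent excess (0 for non-planted members; a
stationary AR(1) process with mean ``excess_shift`` and SD ``excess_sd``
for planted members), ``v`` is a mean-zero AR(1) member frailty with
variance ``noise_persistent_share * sigma_noise**2``, and ``w`` is iid
noise carrying the remaining variance, so the single-year noise SD is
exactly ``sigma_noise``.  Both AR(1) processes share ``persistence_rho``.

Analysis inputs (members, claims, ppe tables) never contain the latent
columns; those live only in the truth sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SETTINGS = ["inpatient", "emergency", "professional", "pharmacy", "other"]

# Baseline share of spending routed to each setting; each member-year gets
# Dirichlet-perturbed shares so setting mix is a stable member trait.
SETTING_SHARES = np.array([0.25, 0.08, 0.32, 0.25, 0.10])
SETTING_CONCENTRATION = 25.0

# Synthetic condition categories: prevalence and true log10-scale effects.
DEFAULT_PREVALENCE: dict[str, float] = {
    "HTN": 0.22, "CKD": 0.04, "DIAB": 0.12, "COPD": 0.07, "ASTHMA": 0.08,
    "MOOD": 0.30, "PSYCH": 0.08, "SUBST": 0.20, "CANCER": 0.03,
    "INJURY": 0.10, "CARDIAC": 0.06, "MSK": 0.18, "GEN": 1.0,
}

DEFAULT_BETA: dict[str, float] = {
    "intercept": 2.05,
    "age": 0.004,
    "sex_M": -0.05,
    "disabled": 0.30,
    "HTN": 0.20, "CKD": 0.60, "DIAB": 0.30, "COPD": 0.28, "ASTHMA": 0.15,
    "MOOD": 0.35, "PSYCH": 0.45, "SUBST": 0.30, "CANCER": 0.70,
    "INJURY": 0.12, "CARDIAC": 0.45, "MSK": 0.15, "GEN": 0.0,
    # county and plan effects
    "county_C02": 0.03, "county_C03": -0.03, "county_C04": 0.05,
    "county_C05": -0.05, "county_C06": 0.02, "county_C07": -0.02,
    "county_C08": 0.04,
    "plan_MCO_A": 0.05, "plan_MCO_B": -0.05,
    "race_black": 0.0, "race_hispanic": 0.0, "race_amindian": 0.0,
    "race_asian": 0.0, "race_unknown": 0.0,
}

# Two-column diagnosis-to-category mapping (emulating a CCS-style grouper).
# CKD carries a severity gradient (5851 early .. 5856 end-stage renal
# disease); HTN has two codes whose mix does NOT shift with excess, so the
# within-code variance mechanism dominates there.
DEFAULT_DX_MAPPING: dict[str, str] = {
    "4011": "HTN", "4019": "HTN",
    "5851": "CKD", "5852": "CKD", "5853": "CKD", "5854": "CKD",
    "5855": "CKD", "5856": "CKD",
    "25000": "DIAB", "25002": "DIAB",
    "4910": "COPD", "4928": "COPD",
    "49390": "ASTHMA", "49392": "ASTHMA",
    "2962": "MOOD", "3004": "MOOD",
    "2953": "PSYCH", "29530": "PSYCH",
    "3040": "SUBST", "30500": "SUBST",
    "1749": "CANCER", "1629": "CANCER",
    "95901": "INJURY", "8470": "INJURY",
    "4280": "CARDIAC", "41401": "CARDIAC",
    "7242": "MSK", "71590": "MSK",
    "V700": "GEN",
}


@dataclass
class CodeMixture:
    """Per-category code assignment model.

    ``codes`` are drawn with ``base_probs``; if ``coupling`` is nonzero the
    last code is treated as the high-severity code whose assignment
    probability follows a logistic link in the member's unexplained
    propensity (latent excess + frailty), with the remaining codes sharing
    the leftover probability proportionally.
    """

    codes: list[str]
    base_probs: list[float]
    coupling: float = 0.0

    def severe_prob(self, propensity: np.ndarray) -> np.ndarray:
        p0 = self.base_probs[-1]
        logit = math.log(p0 / (1.0 - p0)) + self.coupling * propensity
        return 1.0 / (1.0 + np.exp(-logit))


def default_code_mixture() -> dict[str, CodeMixture]:
    mix: dict[str, CodeMixture] = {}
    by_cat: dict[str, list[str]] = {}
    for code, cat in DEFAULT_DX_MAPPING.items():
        by_cat.setdefault(cat, []).append(code)
    for cat, codes in by_cat.items():
        probs = [1.0 / len(codes)] * len(codes)
        mix[cat] = CodeMixture(codes=sorted(codes), base_probs=probs)
    # hypertension: stable 20/80 split between benign and unspecified
    mix["HTN"] = CodeMixture(codes=["4011", "4019"], base_probs=[0.2, 0.8])
    # chronic kidney disease: end-stage share rises with excess utilization
    mix["CKD"] = CodeMixture(
        codes=["5851", "5852", "5853", "5854", "5855", "5856"],
        base_probs=[0.25, 0.20, 0.15, 0.10, 0.05, 0.25],
        coupling=2.0,
    )
    return mix


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic panel.

    All effects and noise scales are on the log10 PMPM scale.
    """

    n_members: int = 20_000
    years: list[int] = field(default_factory=lambda: [2011, 2012, 2013, 2014])
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_noise: float = 0.30
    excess_fraction: float = 0.05
    excess_shift: float = 0.90          # 3 * sigma_noise
    excess_sd: float = 0.05             # spread of the planted component
    persistence_rho: float = 0.5
    noise_persistent_share: float = 0.4  # frailty share of sigma_noise**2
    ppe_coupling: float = 1.0
    ppe_cost_share: float = 0.5         # share of propensity passed into per-event cost
    ppr_base_rate: float = 0.15
    ppv_base_rate: float = 1.0
    ppr_event_cost: float = 4000.0      # median per-event cost, log-normal
    ppv_event_cost: float = 600.0
    event_cost_sigma: float = 0.5       # natural-log SD of per-event cost
    claims_rate: float = 1.0            # extra claims per category ~ Poisson
    code_mixture: dict[str, CodeMixture] = field(default_factory=default_code_mixture)
    seed: int = 0

    def validate(self) -> None:
        if self.n_members <= 0:
            raise ValueError("n_members must be positive")
        if not self.years:
            raise ValueError("years must be non-empty")
        for name, val in [
            ("excess_fraction", self.excess_fraction),
            ("noise_persistent_share", self.noise_persistent_share),
        ]:
            if not (0.0 <= val <= 1.0) or not np.isfinite(val):
                raise ValueError(f"{name} must be in [0, 1]")
        for cat, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence[{cat}] must be in [0, 1]")
        if not (self.sigma_noise > 0 and np.isfinite(self.sigma_noise)):
            raise ValueError("sigma_noise must be positive")
        if not (abs(self.persistence_rho) < 1):
            raise ValueError("|persistence_rho| must be < 1")
        if self.ppe_coupling < 0:
            raise ValueError("ppe_coupling must be non-negative")
        if self.excess_shift < 0 or self.excess_sd < 0:
            raise ValueError("excess_shift and excess_sd must be non-negative")


@dataclass
class SyntheticData:
    """Bundle of generated tables plus the hidden-truth sidecar."""

    members: pd.DataFrame
    claims: pd.DataFrame
    ppe: pd.DataFrame
    truth: pd.DataFrame
    mapping: pd.DataFrame
    config: GeneratorConfig


def _rngs(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """One substream per stage, spawned in documented order from the seed."""
    ss = np.random.SeedSequence(config.seed)
    members_ss, claims_ss, ppe_ss = ss.spawn(3)
    return {
        "members": np.random.default_rng(members_ss),
        "claims": np.random.default_rng(claims_ss),
        "ppe": np.random.default_rng(ppe_ss),
    }


def _ar1_panel(rng: np.random.Generator, n: int, n_years: int,
               mean: float | np.ndarray, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) draws, shape (n, n_years), marginal N(mean, sd^2)."""
    out = np.empty((n, n_years))
    out[:, 0] = mean + sd * rng.standard_normal(n)
    innov_sd = sd * math.sqrt(max(1.0 - rho * rho, 0.0))
    for t in range(1, n_years):
        out[:, t] = mean + rho * (out[:, t - 1] - mean) + innov_sd * rng.standard_normal(n)
    return out


def generate_members(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the member-year panel and the latent-truth sidecar.

    Returns ``(members, truth)``.  ``members`` has one row per member per
    year with demographics, enrollment, pregnancy flag and condition
    categories (as a '|'-joined string column); ``truth`` carries, per
    member-year, the planted flag, the latent excess ``u``, the persistent
    frailty ``v`` and the transient noise ``w`` used for expenditures.
    """
    config.validate()
    rng = _rngs(config)["members"]
    n, years = config.n_members, list(config.years)
    n_years = len(years)

    member_id = np.array([f"M{i:07d}" for i in range(n)])
    age0 = rng.integers(16, 63, size=n)
    sex = rng.choice(["F", "M"], size=n, p=[0.6, 0.4])
    race = rng.choice(
        ["white", "black", "hispanic", "amindian", "asian", "unknown"],
        size=n, p=[0.26, 0.21, 0.38, 0.002, 0.016, 0.132])
    disabled = rng.random(n) < 0.45
    county = rng.choice([f"C{i:02d}" for i in range(1, 9)], size=n)
    plan = rng.choice(["FFS", "MCO_A", "MCO_B"], size=n, p=[0.3, 0.4, 0.3])

    cats = sorted(config.prevalence)
    has_cat = {c: rng.random(n) < config.prevalence[c] for c in cats}
    cat_strings = [
        "|".join(c for c in cats if has_cat[c][i]) for i in range(n)
    ]

    planted = rng.random(n) < config.excess_fraction
    u = np.zeros((n, n_years))
    if planted.any() and config.excess_fraction > 0:
        u_p = _ar1_panel(rng, int(planted.sum()), n_years,
                         config.excess_shift, config.excess_sd,
                         config.persistence_rho)
        u[planted] = u_p
    frailty_sd = config.sigma_noise * math.sqrt(config.noise_persistent_share)
    transient_sd = config.sigma_noise * math.sqrt(1.0 - config.noise_persistent_share)
    v = _ar1_panel(rng, n, n_years, 0.0, frailty_sd, config.persistence_rho)
    w = transient_sd * rng.standard_normal((n, n_years))

    member_rows, truth_rows = [], []
    for t, year in enumerate(years):
        months = np.where(rng.random(n) < 0.7, 12, rng.integers(1, 13, size=n))
        age = age0 + t
        pregnant = (sex == "F") & (age < 45) & (rng.random(n) < 0.04)
        member_rows.append(pd.DataFrame({
            "member_id": member_id, "year": year, "age": age, "sex": sex,
            "race": race, "disabled": disabled, "county": county,
            "plan": plan, "months_enrolled": months, "pregnant": pregnant,
            "condition_categories": cat_strings,
        }))
        truth_rows.append(pd.DataFrame({
            "member_id": member_id, "year": year, "planted": planted,
            "latent_excess": u[:, t], "frailty": v[:, t], "transient": w[:, t],
        }))
    members = pd.concat(member_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return members, truth


def _linear_predictor(members: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    """True mean of log10 PMPM from the configured effects."""
    eta = np.full(len(members), beta.get("intercept", 0.0))
    eta += beta.get("age", 0.0) * members["age"].to_numpy(float)
    eta += np.where(members["sex"].to_numpy() == "M", beta.get("sex_M", 0.0), 0.0)
    eta += np.where(members["disabled"].to_numpy(bool), beta.get("disabled", 0.0), 0.0)
    for col, prefix in [("county", "county_"), ("plan", "plan_"), ("race", "race_")]:
        vals = members[col].astype(str)
        eta += vals.map(lambda v, p=prefix: beta.get(p + v, 0.0)).to_numpy(float)
    cat_lists = members["condition_categories"].str.split("|")
    cat_effect = cat_lists.map(
        lambda cs: sum(beta.get(c, 0.0) for c in cs if c))
    eta += cat_effect.to_numpy(float)
    return eta


def generate_claims(members: pd.DataFrame, config: GeneratorConfig,
                    truth: pd.DataFrame) -> pd.DataFrame:
    """Generate claim lines whose per-member totals follow the cost model.

    Every member-year receives at least one claim per condition category
    (plus the universal wellness category), each claim gets a setting and
    a principal diagnosis code, and paid amounts are scaled so that they
    sum exactly to the member's total annual expenditure
    ``PMPM * months_enrolled`` with ``log10 PMPM = beta.x + u + v + w``.
    """
    if len(members) == 0:
        raise ValueError("empty member table")
    config.validate()
    rng = _rngs(config)["claims"]

    tr = truth.set_index(["member_id", "year"])
    idx = pd.MultiIndex.from_frame(members[["member_id", "year"]])
    u = tr["latent_excess"].reindex(idx).to_numpy(float)
    v = tr["frailty"].reindex(idx).to_numpy(float)
    w = tr["transient"].reindex(idx).to_numpy(float)
    propensity = u + v

    eta = _linear_predictor(members, config.beta)
    log10_pmpm = eta + u + v + w
    total = (10.0 ** log10_pmpm) * members["months_enrolled"].to_numpy(float)

    n_rows = len(members)
    cat_lists = [
        [c for c in s.split("|") if c] or ["GEN"]
        for s in members["condition_categories"].to_numpy()
    ]
    cat_counts = np.array([len(c) for c in cat_lists])
    pair_row = np.repeat(np.arange(n_rows), cat_counts)
    pair_cat = np.array([c for cs in cat_lists for c in cs], dtype=object)

    # at least one claim per (member-year, category), extras Poisson
    n_per_pair = 1 + rng.poisson(config.claims_rate, size=len(pair_cat))
    claim_row = np.repeat(pair_row, n_per_pair)
    claim_cat = np.repeat(pair_cat, n_per_pair)
    n_claims = len(claim_row)
    prop_claim = propensity[claim_row]

    codes = np.empty(n_claims, dtype=object)
    for cat in sorted(set(claim_cat.tolist())):
        sel = claim_cat == cat
        k = int(sel.sum())
        mix = config.code_mixture.get(cat)
        if mix is None:
            codes[sel] = "UNK"
            continue
        if mix.coupling != 0.0:
            p_sev = mix.severe_prob(prop_claim[sel])
            severe = rng.random(k) < p_sev
            rest = np.array(mix.base_probs[:-1], float)
            rest_codes = rng.choice(mix.codes[:-1], size=k, p=rest / rest.sum())
            codes[sel] = np.where(severe, mix.codes[-1], rest_codes)
        else:
            codes[sel] = rng.choice(mix.codes, size=k,
                                    p=np.array(mix.base_probs, float))

    # member-year setting propensities, then per-claim assignment
    shares = rng.dirichlet(SETTING_SHARES * SETTING_CONCENTRATION, size=n_rows)
    cum = np.cumsum(shares, axis=1)
    setting_idx = (rng.random(n_claims)[:, None] > cum[claim_row]).sum(axis=1)
    settings = np.array(SETTINGS, dtype=object)[setting_idx]

    weights = rng.lognormal(0.0, 0.7, size=n_claims)
    weight_sum = np.bincount(claim_row, weights=weights, minlength=n_rows)
    amounts = total[claim_row] * weights / weight_sum[claim_row]
    # enforce exact conservation against floating-point dust: adjust the
    # last claim of each member-year (claim_row is sorted ascending and
    # every member-year has at least one claim)
    last = np.r_[claim_row[1:] != claim_row[:-1], True]
    sums = np.bincount(claim_row, weights=amounts, minlength=n_rows)
    amounts[last] += total - sums

    claims = pd.DataFrame({
        "member_id": members["member_id"].to_numpy()[claim_row],
        "year": members["year"].to_numpy()[claim_row],
        "setting": settings,
        "principal_dx": codes,
        "paid_amount": amounts,
    })
    return claims


def generate_ppe(members: pd.DataFrame, config: GeneratorConfig,
                 truth: pd.DataFrame) -> pd.DataFrame:
    """Generate preventable-event records (readmissions and ED visits).

    Counts are Poisson with a log-link in the member's unexplained
    propensity (latent excess + frailty): rate = base * exp(coupling * (u+v)).
    Expenditures are count x log-normal per-event cost whose median also
    scales as 10^(coupling * cost_share * (u+v)) — over-utilizers' events
    are both more frequent and costlier; zero count implies zero
    expenditure, and ppe_coupling = 0 decouples counts and costs alike.
    """
    config.validate()
    if config.ppe_coupling < 0:
        raise ValueError("ppe_coupling must be non-negative")
    rng = _rngs(config)["ppe"]

    tr = truth.set_index(["member_id", "year"])
    idx = pd.MultiIndex.from_frame(members[["member_id", "year"]])
    propensity = (tr["latent_excess"].reindex(idx).to_numpy(float)
                  + tr["frailty"].reindex(idx).to_numpy(float))

    lift = np.exp(config.ppe_coupling * propensity)
    ppr_count = rng.poisson(config.ppr_base_rate * lift)
    ppv_count = rng.poisson(config.ppv_base_rate * lift)
    log_cost_shift = (math.log(10.0) * config.ppe_coupling
                      * config.ppe_cost_share * propensity)

    def _expenditure(counts: np.ndarray, median_cost: float) -> np.ndarray:
        out = np.zeros(len(counts))
        pos = counts > 0
        # sum of k log-normal event costs, member-specific median
        for k in np.unique(counts[pos]):
            sel = counts == k
            mu = math.log(median_cost) + log_cost_shift[sel]
            draws = rng.lognormal(mu[:, None], config.event_cost_sigma,
                                  size=(int(sel.sum()), int(k)))
            out[sel] = draws.sum(axis=1)
        return out

    ppe = pd.DataFrame({
        "member_id": members["member_id"].to_numpy(),
        "year": members["year"].to_numpy(),
        "ppr_count": ppr_count,
        "ppr_expenditure": _expenditure(ppr_count, config.ppr_event_cost),
        "ppv_count": ppv_count,
        "ppv_expenditure": _expenditure(ppv_count, config.ppv_event_cost),
    })
    return ppe


def mapping_table(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Two-column (code, category) diagnosis-grouping table."""
    mapping = DEFAULT_DX_MAPPING if config is None else {
        code: cat
        for cat, mix in config.code_mixture.items()
        for code in mix.codes
    }
    return (pd.DataFrame(sorted(mapping.items()), columns=["code", "category"])
            .reset_index(drop=True))


def simulate(config: GeneratorConfig) -> SyntheticData:
    """Run the full generator: members, claims, PPE records, truth, mapping."""
    members, truth = generate_members(config)
    claims = generate_claims(members, config, truth)
    ppe = generate_ppe(members, config, truth)
    return SyntheticData(members=members, claims=claims, ppe=ppe,
                         truth=truth, mapping=mapping_table(), config=config)


def write_tables(data: SyntheticData, outdir: str | Path,
                 columnar: bool = False) -> dict[str, Path]:
    """Write analysis inputs plus the truth sidecar.

    The members/claims/ppe tables are the analysis inputs and contain no
    latent columns; 'truth.csv' is the sidecar for evaluation only.  With
    ``columnar=True`` a Parquet copy is written alongside each CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("members", data.members), ("claims", data.claims),
                     ("ppe", data.ppe), ("truth", data.truth),
                     ("dx_mapping", data.mapping)]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        if columnar:
            df.to_parquet(outdir / f"{name}.parquet", index=False)
        paths[name] = p
    return paths
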