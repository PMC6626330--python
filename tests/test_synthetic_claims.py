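"""Generator contracts: determinism, planted structure, conservation."""

import math

import numpy as np
import pandas as pd
import pytest

import highutil as hu
from highutil.synthetic_claims import _linear_predictor


def test_same_seed_gives_identical_tables():
    cfg = hu.GeneratorConfig(n_members=400, years=[2011, 2012], seed=42)
    a = hu.simulate(cfg)
    b = hu.simulate(hu.GeneratorConfig(n_members=400, years=[2011, 2012], seed=42))
    for name in ("members", "claims", "ppe", "truth"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


def test_different_seed_changes_output():
    cfg = dict(n_members=200, years=[2011])
    a = hu.simulate(hu.GeneratorConfig(**cfg, seed=1))
    b = hu.simulate(hu.GeneratorConfig(**cfg, seed=2))
    assert not a.truth["transient"].equals(b.truth["transient"])


def test_degenerate_mixture_has_zero_latent():
    cfg = hu.GeneratorConfig(n_members=500, excess_fraction=0.0, seed=3)
    _, truth = hu.generate_members(cfg)
    assert (truth["latent_excess"] == 0).all()
    assert not truth["planted"].any()


def test_truth_separated_from_analysis_tables(small_data):
    hidden = {"latent_excess", "frailty", "transient", "planted"}
    for table in (small_data.members, small_data.claims, small_data.ppe):
        assert hidden.isdisjoint(table.columns)
    assert {"latent_excess", "planted"} <= set(small_data.truth.columns)


def test_member_counts_and_enrollment(small_data, small_config):
    counts = small_data.members.groupby("year").size()
    assert (counts == small_config.n_members).all()
    assert small_data.members["months_enrolled"].between(1, 12).all()


def test_planted_fraction_near_config(small_data, small_config):
    per_member = small_data.truth.groupby("member_id")["planted"].first()
    frac = per_member.mean()
    n = len(per_member)
    se = math.sqrt(0.05 * 0.95 / n)
    assert abs(frac - small_config.excess_fraction) < 4 * se


def test_latent_ar1_correlation_matches_rho():
    """Year-to-year correlation of the planted latent process is rho."""
    cfg = hu.GeneratorConfig(n_members=50_000, years=[2011, 2012],
                             excess_fraction=0.3, persistence_rho=0.5, seed=5)
    _, truth = hu.generate_members(cfg)
    wide = truth.pivot(index="member_id", columns="year", values="latent_excess")
    planted = truth.groupby("member_id")["planted"].first()
    sub = wide[planted]
    r = np.corrcoef(sub[2011], sub[2012])[0, 1]
    assert abs(r - 0.5) < 0.02


def test_frailty_ar1_correlation_matches_rho(small_data, small_config):
    wide = small_data.truth.pivot(index="member_id", columns="year",
                                  values="frailty")
    r = np.corrcoef(wide[2011], wide[2012])[0, 1]
    assert abs(r - small_config.persistence_rho) < 0.05


def test_claims_conserve_member_totals(small_data, small_config):
    """Sum of claim lines equals the cost model's member-year total."""
    truth = small_data.truth.set_index(["member_id", "year"])
    members = small_data.members
    idx = pd.MultiIndex.from_frame(members[["member_id", "year"]])
    eta = _linear_predictor(members, small_config.beta)
    log10_pmpm = (eta + truth["latent_excess"].reindex(idx).to_numpy()
                  + truth["frailty"].reindex(idx).to_numpy()
                  + truth["transient"].reindex(idx).to_numpy())
    expected = pd.Series(
        10.0 ** log10_pmpm * members["months_enrolled"].to_numpy(float),
        index=idx)
    got = small_data.claims.groupby(["member_id", "year"])["paid_amount"].sum()
    np.testing.assert_allclose(got.reindex(expected.index), expected,
                               rtol=1e-12)


def test_noiseless_limit_recovers_intercept():
    beta = {"intercept": 2.0}
    cfg = hu.GeneratorConfig(
        n_members=200, years=[2011], beta=beta, sigma_noise=1e-12,
        excess_fraction=0.0, seed=9,
        prevalence={"GEN": 1.0},
    )
    data = hu.simulate(cfg)
    tot = data.claims.groupby("member_id")["paid_amount"].sum()
    months = data.members.set_index("member_id")["months_enrolled"]
    log10_pmpm = np.log10(tot / months.reindex(tot.index))
    np.testing.assert_allclose(log10_pmpm, 2.0, atol=1e-6)


def test_nonplanted_mean_matches_analytic_expectation(small_data, small_config):
    """Mean log10 PMPM of non-planted members sits at beta.x on average."""
    members = small_data.members[small_data.members.year == 2011]
    truth = small_data.truth[small_data.truth.year == 2011].set_index("member_id")
    nonplanted = truth.index[~truth["planted"]]
    sub = members[members.member_id.isin(nonplanted)]
    eta = _linear_predictor(sub, small_config.beta)
    tot = (small_data.claims[small_data.claims.year == 2011]
           .groupby("member_id")["paid_amount"].sum())
    months = sub.set_index("member_id")["months_enrolled"]
    observed = np.log10(tot.reindex(months.index) / months)
    se = small_config.sigma_noise / math.sqrt(len(sub))
    assert abs(observed.mean() - eta.mean()) < 3 * se


def test_mixture_shift_decoupled_when_coupling_zero():
    cfg = hu.GeneratorConfig(n_members=50_000, years=[2011], seed=21)
    cfg.code_mixture["CKD"].coupling = 0.0
    cfg.prevalence["CKD"] = 0.5  # enough kidney-disease members to measure
    data = hu.simulate(cfg)
    ckd = data.claims[data.claims.principal_dx.str.startswith("585")]
    severe_share = (ckd.assign(severe=ckd.principal_dx == "5856")
                    .groupby("member_id")["severe"].mean())
    latent = data.truth.set_index("member_id")["latent_excess"]
    frailty = data.truth.set_index("member_id")["frailty"]
    prop = (latent + frailty).reindex(severe_share.index)
    r = np.corrcoef(severe_share, prop)[0, 1]
    assert abs(r) < 0.02


def test_ppe_zero_count_zero_expenditure(small_data):
    ppe = small_data.ppe
    assert (ppe.loc[ppe.ppr_count == 0, "ppr_expenditure"] == 0).all()
    assert (ppe.loc[ppe.ppv_count == 0, "ppv_expenditure"] == 0).all()
    assert (ppe[["ppr_count", "ppv_count"]] >= 0).all().all()


def test_ppe_decoupled_when_coupling_zero():
    cfg = hu.GeneratorConfig(n_members=50_000, years=[2011],
                             ppe_coupling=0.0, seed=31)
    members, truth = hu.generate_members(cfg)
    ppe = hu.generate_ppe(members, cfg, truth)
    latent = truth.set_index("member_id")["latent_excess"]
    counts = ppe.set_index("member_id")["ppr_count"].reindex(latent.index)
    r = np.corrcoef(latent, counts)[0, 1]
    assert abs(r) < 0.02


def test_ppe_planted_rate_ratio_matches_closed_form():
    """Poisson log-link: planted/non-planted mean count ratio is
    exp(c*m + c^2*tau^2/2); the frailty factor cancels between groups."""
    cfg = hu.GeneratorConfig(n_members=50_000, years=[2011],
                             excess_fraction=0.3, ppe_coupling=1.0, seed=41)
    members, truth = hu.generate_members(cfg)
    ppe = hu.generate_ppe(members, cfg, truth).set_index("member_id")
    t = truth.set_index("member_id")
    mean_p = ppe.loc[t.planted, "ppv_count"].mean()
    mean_n = ppe.loc[~t.planted, "ppv_count"].mean()
    expected = math.exp(cfg.ppe_coupling * cfg.excess_shift
                        + (cfg.ppe_coupling * cfg.excess_sd) ** 2 / 2)
    assert abs(mean_p / mean_n - expected) / expected < 0.10


@pytest.mark.parametrize("field, value", [
    ("sigma_noise", -1.0),
    ("excess_fraction", 1.5),
    ("persistence_rho", 1.0),
    ("n_members", 0),
    ("ppe_coupling", -0.5),
])
def test_invalid_config_rejected(field, value):
    cfg = hu.GeneratorConfig(**{field: value})
    with pytest.raises(ValueError):
        cfg.validate()


def test_normality_of_true_residuals_without_planting():
    """With no planted members the generating noise is normal each year."""
    from scipy import stats
    cfg = hu.GeneratorConfig(n_members=2000, years=[2011],
                             excess_fraction=0.0, seed=17)
    _, truth = hu.generate_members(cfg)
    noise = truth["frailty"] + truth["transient"]
    z = (noise - noise.mean()) / noise.std()
    _, p = stats.normaltest(z)
    assert p > 0.01


def test_write_tables_round_trip(tmp_path, small_data):
    paths = hu.write_tables(small_data, tmp_path)
    assert set(paths) == {"members", "claims", "ppe", "truth", "dx_mapping"}
    reread = pd.read_csv(paths["claims"], dtype={"principal_dx": str})
    assert len(reread) == len(small_data.claims)
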