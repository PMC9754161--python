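"""Synthetic cohort generator: determinism, marginals, missingness, oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from iopw.simulate import (
    CovariateSpec,
    MissingnessSpec,
    SimulationConfig,
    generate_cohorts,
    impose_missingness,
    oracle_marginal_hr,
    table_like_config,
)
from iopw.survival import fit_weighted_cox
from iopw.weights import design_matrix

from conftest import make_config


def test_schema_and_sizes():
    cfg = make_config(n_original=500, n_target=300)
    coh, _ = generate_cohorts(cfg)
    assert len(coh) == 800
    assert (coh["S"] == 1).sum() == 500 and (coh["S"] == 0).sum() == 300
    target = coh[coh["S"] == 0]
    assert target[["A", "time", "event"]].isna().all().all()
    orig = coh[coh["S"] == 1]
    assert orig[["A", "time", "event"]].notna().all().all()
    assert (orig["time"] > 0).all()
    assert set(orig["event"].unique()) <= {0.0, 1.0}


def test_determinism_byte_identical(tmp_path):
    cfg = make_config(seed=7, missingness=[MissingnessSpec("x1", rate=0.1)])
    a, _ = generate_cohorts(cfg)
    b, _ = generate_cohorts(cfg)
    am = impose_missingness(a, cfg)
    bm = impose_missingness(b, cfg)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    am.to_csv(pa, index=False)
    bm.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()


def test_treatment_marginal_without_confounding():
    cfg = make_config(n_original=10_000, n_target=0, gamma={}, seed=1)
    cfg.treatment_model["intercept"] = 0.4
    coh, _ = generate_cohorts(cfg)
    p = expit(0.4)
    se = np.sqrt(p * (1 - p) / 10_000)
    assert abs(coh["A"].mean() - p) < 3 * se


def test_naive_cox_recovers_generating_hr():
    # unconfounded, uncensored, no covariate effects: conditional = marginal
    cfg = make_config(n_original=20_000, n_target=0, beta_treatment=np.log(1.5), seed=3)
    coh, _ = generate_cohorts(cfg)
    fit = fit_weighted_cox(coh["time"], coh["event"], coh["A"])
    assert abs(fit.log_hr - np.log(1.5)) < 3 * fit.se_model


def test_missingness_identity_when_no_rates():
    cfg = make_config(seed=5)
    coh, _ = generate_cohorts(cfg)
    assert impose_missingness(coh, cfg).equals(coh)


def test_missingness_rate_binomial():
    cfg = make_config(
        n_original=10_000, n_target=0, missingness=[MissingnessSpec("x1", rate=0.29)], seed=9
    )
    coh, _ = generate_cohorts(cfg)
    frac = impose_missingness(coh, cfg)["x1"].isna().mean()
    se = np.sqrt(0.29 * 0.71 / 10_000)
    assert abs(frac - 0.29) < 3 * se


def test_mar_missingness_by_treatment_arm():
    ms = MissingnessSpec("x2", depends_on="A", rates={1.0: 0.4, 0.0: 0.1})
    cfg = make_config(n_original=10_000, n_target=0, missingness=[ms], seed=11)
    coh, _ = generate_cohorts(cfg)
    out = impose_missingness(coh, cfg)
    for arm, rate in ((1.0, 0.4), (0.0, 0.1)):
        sub = out[out["A"] == arm]
        se = np.sqrt(rate * (1 - rate) / len(sub))
        assert abs(sub["x2"].isna().mean() - rate) < 3 * se
    # the outcome columns are never blanked
    assert out[["S", "A", "time", "event"]].notna().all().all()


def test_mar_on_variable_with_missingness_rejected():
    cfg = make_config(
        missingness=[
            MissingnessSpec("x1", rate=0.1),
            MissingnessSpec("x2", depends_on="x1", rates={0.0: 0.1, "default": 0.2}),
        ]
    )
    with pytest.raises(ValueError, match="verifiable"):
        cfg.validate()


def test_oracle_null_effect_is_one():
    cfg = make_config(beta_treatment=0.0, beta_cov={"x1": 0.5}, seed=13)
    _, truth = generate_cohorts(cfg)
    hr = oracle_marginal_hr(truth, "original", n_mc=20_000, seed=1)
    assert abs(np.log(hr)) < 0.05


def test_oracle_equals_conditional_without_heterogeneity():
    cfg = make_config(beta_treatment=np.log(1.5), beta_cov={}, seed=13)
    _, truth = generate_cohorts(cfg)
    hr = oracle_marginal_hr(truth, "original", n_mc=20_000, seed=2)
    assert abs(np.log(hr) - np.log(1.5)) < 0.05


def test_oracle_interaction_sign():
    # positive interaction with x1, target shifted up in x1 -> larger target HR
    cfg = make_config(
        beta_treatment=0.0, interactions={"x1": 0.5}, target_shift=1.0, seed=17
    )
    _, truth = generate_cohorts(cfg)
    hr_o = oracle_marginal_hr(truth, "original", n_mc=20_000, seed=3)
    hr_t = oracle_marginal_hr(truth, "target", n_mc=20_000, seed=4)
    assert hr_t > hr_o


def test_marginalization_without_interactions():
    # different covariate distributions but no effect modification:
    # marginal HRs agree across populations up to MC noise
    cfg = make_config(
        beta_treatment=np.log(1.4), beta_cov={"x1": 0.3}, target_shift=0.8, seed=19
    )
    _, truth = generate_cohorts(cfg)
    hr_o = oracle_marginal_hr(truth, "original", n_mc=30_000, seed=5)
    hr_t = oracle_marginal_hr(truth, "target", n_mc=30_000, seed=6)
    assert abs(np.log(hr_o) - np.log(hr_t)) < 0.05


def test_selection_model_refit_recovers_coefficients():
    cfg = make_config(
        n_original=10_000,
        n_target=10_000,
        selection={"intercept": 0.0, "coef": {"x1": 1.0}},
        seed=23,
    )
    coh, _ = generate_cohorts(cfg)
    import statsmodels.api as sm

    X = design_matrix(coh, ["x1", "x2"])
    res = sm.Logit(coh["S"].astype(float), X).fit(disp=0)
    assert abs(res.params["x1"] - 1.0) < 3 * res.bse["x1"]
    assert abs(res.params["x2"]) < 3 * res.bse["x2"]
    # selection skews the original cohort's modifier distribution upward
    assert coh.groupby("S")["x1"].mean()[1] > coh.groupby("S")["x1"].mean()[0]


def test_config_validation_errors():
    with pytest.raises(ValueError):
        make_config(n_original=1).validate()
    cfg = make_config()
    cfg.outcome_model["lambda0"] = -1.0
    with pytest.raises(ValueError):
        cfg.validate()
    cfg2 = make_config(missingness=[MissingnessSpec("x1", rate=1.5)])
    with pytest.raises(ValueError):
        cfg2.validate()
    cfg3 = make_config()
    cfg3.censoring["horizon"] = 0.0
    with pytest.raises(ValueError):
        cfg3.validate()


def test_table_like_config_generates():
    cfg = table_like_config(n_original=300, n_target=600, seed=1)
    coh, _ = generate_cohorts(cfg)
    out = impose_missingness(coh, cfg)
    assert len(out) == 900
    assert out["ecog"].isna().mean() > 0.15  # ~29% nominal
    assert set(out["race"].dropna()) <= {"white", "black", "asian", "other"}


def test_roundtrip_config_from_dict():
    cfg = make_config(seed=3)
    from dataclasses import asdict

    cfg2 = SimulationConfig.from_dict(asdict(cfg))
    a, _ = generate_cohorts(cfg)
    b, _ = generate_cohorts(cfg2)
    assert a.equals(b)
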