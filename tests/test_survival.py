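"""Endpoint derivation and weighted Cox / Kaplan-Meier estimation."""

import numpy as np
import pandas as pd
import pytest

from iopw.simulate import generate_cohorts
from iopw.survival import derive_endpoint, fit_weighted_cox, km_weighted, ph_test, plot_km

from conftest import make_config


def _raw(**kw):
    base = {
        "id": 1,
        "therapy_start": "2018-01-01",
        "progression_date": None,
        "death_month": None,
        "last_note_date": "2020-06-01",
    }
    base.update(kw)
    return pd.DataFrame([base])


class TestDeriveEndpoint:
    def test_progression_event_time(self):
        # progression 100 days after therapy start, index at start + 14
        rec = derive_endpoint(_raw(progression_date="2018-04-11")).iloc[0]
        assert rec["time"] == 86
        assert rec["event"] == 1 and rec["event_source"] == "progression"

    def test_three_year_administrative_censoring(self):
        rec = derive_endpoint(
            _raw(therapy_start="2017-01-01", last_note_date="2021-06-01")
        ).iloc[0]
        assert rec["time"] == 1095
        assert rec["event"] == 0 and rec["event_source"] == "censor-3y"

    def test_last_note_censoring(self):
        rec = derive_endpoint(
            _raw(therapy_start="2018-01-01", last_note_date="2018-07-01")
        ).iloc[0]
        assert rec["event_source"] == "censor-lastnote"
        assert rec["time"] == (pd.Timestamp("2018-07-01") - pd.Timestamp("2018-01-15")).days

    def test_death_set_to_fifteenth_of_month(self):
        rec = derive_endpoint(_raw(death_month="2018-03")).iloc[0]
        assert rec["event_source"] == "death"
        assert rec["time"] == (pd.Timestamp("2018-03-15") - pd.Timestamp("2018-01-15")).days

    def test_death_before_index_excluded(self):
        # death lands on the 15th, 10 days after therapy start (before index)
        out = derive_endpoint(_raw(therapy_start="2018-03-05", death_month="2018-03")).iloc[0]
        assert out["excluded"]
        assert out["exclusion_reason"] == "event_on_or_before_index"

    def test_death_month_before_therapy_start_flagged(self):
        out = derive_endpoint(_raw(therapy_start="2018-05-01", death_month="2018-02")).iloc[0]
        assert out["excluded"]
        assert out["exclusion_reason"] == "death_before_therapy_start"

    def test_progression_and_death_take_earlier(self):
        rec = derive_endpoint(
            _raw(progression_date="2018-02-20", death_month="2018-06")
        ).iloc[0]
        assert rec["event_source"] == "progression"

    def test_missing_last_note_without_event_errors(self):
        with pytest.raises(ValueError, match="no last note"):
            derive_endpoint(_raw(last_note_date=None))


def test_unit_weights_match_unweighted_fit():
    cfg = make_config(n_original=1000, n_target=0, beta_treatment=0.3, seed=8, horizon=800.0)
    coh, _ = generate_cohorts(cfg)
    f0 = fit_weighted_cox(coh["time"], coh["event"], coh["A"])
    f1 = fit_weighted_cox(coh["time"], coh["event"], coh["A"], np.ones(len(coh)))
    assert f1.log_hr == pytest.approx(f0.log_hr, abs=1e-8)
    assert f1.se_model == pytest.approx(f0.se_model, abs=1e-8)


def test_weight_scale_invariance():
    rng = np.random.default_rng(9)
    n = 400
    A = rng.binomial(1, 0.5, n)
    t = rng.exponential(1 / (0.01 * np.exp(0.3 * A)))
    e = np.ones(n)
    w = rng.uniform(0.5, 2.0, n)
    f1 = fit_weighted_cox(t, e, A, w)
    f2 = fit_weighted_cox(t, e, A, 5.0 * w)
    assert f2.log_hr == pytest.approx(f1.log_hr, abs=1e-10)
    assert f2.se_robust == pytest.approx(f1.se_robust, abs=1e-10)


def test_zero_weight_rows_dropped():
    rng = np.random.default_rng(10)
    n = 300
    A = rng.binomial(1, 0.5, n)
    t = rng.exponential(100, n)
    e = np.ones(n)
    w = np.ones(n)
    w[:50] = 0.0
    f = fit_weighted_cox(t, e, A, w)
    assert f.n == n - 50


def test_cox_error_conditions():
    with pytest.raises(ValueError, match="no events"):
        fit_weighted_cox([1.0, 2.0], [0, 0], [0, 1])
    with pytest.raises(ValueError, match="one treatment arm"):
        fit_weighted_cox([1.0, 2.0, 3.0], [1, 1, 1], [1, 1, 1])


def test_ph_test_returns_probability():
    cfg = make_config(n_original=800, n_target=0, beta_treatment=0.3, seed=12, horizon=1000.0)
    coh, _ = generate_cohorts(cfg)
    f = fit_weighted_cox(coh["time"], coh["event"], coh["A"])
    p = ph_test(f)
    assert 0.0 <= p <= 1.0
    assert f.ph_pvalue == p


def test_km_unweighted_matches_empirical_survival():
    rng = np.random.default_rng(11)
    t = rng.exponential(100, 500)
    A = np.zeros(500)
    A[:250] = 1
    out = km_weighted(t, np.ones(500), A)
    for arm in (0, 1):
        curve = out[arm]["curve"]
        tt = np.median(t)
        s_km = curve.loc[curve["time"] <= tt, "survival"].iloc[-1]
        emp = (t[A == arm] > tt).mean()
        assert s_km == pytest.approx(emp, abs=0.01)


def test_km_weight_scale_invariance():
    rng = np.random.default_rng(12)
    t = rng.exponential(100, 300)
    e = rng.binomial(1, 0.8, 300)
    A = rng.binomial(1, 0.5, 300)
    w = rng.uniform(0.5, 2, 300)
    a = km_weighted(t, e, A, w)
    b = km_weighted(t, e, A, 2.0 * w)
    for arm in (0, 1):
        pd.testing.assert_frame_equal(a[arm]["curve"], b[arm]["curve"])


def test_km_plot_returns_axes():
    import matplotlib

    matplotlib.use("Agg")
    rng = np.random.default_rng(14)
    t = rng.exponential(100, 200)
    A = rng.binomial(1, 0.5, 200)
    ax = plot_km(km_weighted(t, np.ones(200), A))
    assert len(ax.lines) == 2


def test_km_exponential_closed_form():
    rng = np.random.default_rng(13)
    lam = 0.01
    t = rng.exponential(1 / lam, 20_000)
    out = km_weighted(t, np.ones_like(t), np.ones_like(t))
    curve = out[1]["curve"]
    for q in (50, 100, 200):
        s_km = curve.loc[curve["time"] <= q, "survival"].iloc[-1]
        assert s_km == pytest.approx(np.exp(-lam * q), abs=0.02)
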