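"""Endpoint derivation and weighted Cox / Kaplan-Meier estimation.

The endpoint is a real-world progression-free survival time: days from an
index date (therapy start + 14 days, chosen because no immediate treatment
effect is expected) to the first documented progression or death.  Death
dates are only known to month granularity and are set to the 15th; patients
are censored at the last clinical note or 3 years (1095 days) after the
index date, whichever comes first; patients whose progression or death falls
on or before the index date are excluded (flagged, not silently dropped).

Hazard ratios come from a weighted Cox partial likelihood with a robust
(sandwich) variance, Efron tie handling, and treatment as the only
covariate; the proportional-hazards assumption is checked with a
Schoenfeld-residual score test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import StatisticalWarning
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "derive_endpoint",
    "CoxFit",
    "fit_weighted_cox",
    "ph_test",
    "km_weighted",
    "plot_km",
]

HORIZON_DAYS = 1095  # 3 years
INDEX_OFFSET_DAYS = 14


def _to_death_date(value):
    """Month-granular death information -> the 15th of that month."""
    if pd.isna(value):
        return pd.NaT
    ts = pd.to_datetime(value)
    return pd.Timestamp(year=ts.year, month=ts.month, day=15)


def derive_endpoint(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive progression-free-survival records from per-patient dates.

    `raw` needs columns therapy_start and last_note_date, plus optional
    progression_date and death_month (any month-identifying date or
    "YYYY-MM" string).  Returns one row per patient with id, time (days from
    index), event, event_source in {progression, death, censor-lastnote,
    censor-3y}, and excluded/exclusion_reason for patients whose event falls
    on or before the index date or who have no follow-up past it.
    """
    required = {"therapy_start", "last_note_date"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw table must contain columns {sorted(required)}")
    out = []
    for _, row in raw.iterrows():
        start = pd.to_datetime(row["therapy_start"])
        index = start + pd.Timedelta(days=INDEX_OFFSET_DAYS)
        prog = pd.to_datetime(row.get("progression_date", pd.NaT))
        death = _to_death_date(row.get("death_month", pd.NaT))
        last_note = pd.to_datetime(row.get("last_note_date", pd.NaT))
        if pd.notna(death) and death < start:
            # recorded death month resolves to before therapy start: data anomaly
            out.append(_rec(row, None, None, None, True, "death_before_therapy_start"))
            continue

        candidates = [(d, src) for d, src in ((prog, "progression"), (death, "death")) if pd.notna(d)]
        event_date, event_src = min(candidates, key=lambda t: t[0]) if candidates else (pd.NaT, None)

        if pd.notna(event_date) and event_date <= index:
            out.append(_rec(row, None, None, None, True, "event_on_or_before_index"))
            continue
        if pd.isna(last_note) and pd.isna(event_date):
            raise ValueError(f"patient {row.get('id', '?')}: no event and no last note date")

        admin = index + pd.Timedelta(days=HORIZON_DAYS)
        censor_date = admin if pd.isna(last_note) else min(last_note, admin)
        if pd.notna(event_date) and event_date <= censor_date:
            time = (event_date - index).days
            out.append(_rec(row, time, 1, event_src, False, None))
        else:
            time = (censor_date - index).days
            src = "censor-3y" if censor_date == admin else "censor-lastnote"
            if time <= 0:
                out.append(_rec(row, None, None, None, True, "no_followup_after_index"))
            else:
                out.append(_rec(row, time, 0, src, False, None))
    return pd.DataFrame(out)


def _rec(row, time, event, source, excluded, reason):
    return {
        "id": row.get("id"),
        "time": time,
        "event": event,
        "event_source": source,
        "excluded": excluded,
        "exclusion_reason": reason,
    }


@dataclass
class CoxFit:
    """A (possibly weighted) treatment-only Cox fit."""

    log_hr: float
    se_model: float
    se_robust: float
    n: int
    n_events: int
    weighted: bool
    ph_pvalue: float | None = None
    model_: object = None  # fitted lifelines CoxPHFitter (robust)
    data_: object = None  # the fitting frame, for residual-based diagnostics

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (
            float(np.exp(self.log_hr - z * self.se_robust)),
            float(np.exp(self.log_hr + z * self.se_robust)),
        )


def fit_weighted_cox(time, event, A, weights=None) -> CoxFit:
    """Weighted Cox partial-likelihood fit with sandwich variance.

    Treatment is the only covariate (the weights carry all adjustment).
    Zero-weight rows are dropped before fitting -- this is how target-cohort
    rows, which carry step-2 weight 0, vanish from the outcome model.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=float),
            "A": np.asarray(A, dtype=float),
        }
    )
    if weights is None:
        w = np.ones(len(df))
        weighted = False
    else:
        w = np.asarray(getattr(weights, "values", weights), dtype=float)
        weighted = True
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    df["w"] = w
    df = df[df["w"] > 0].reset_index(drop=True)
    if df["event"].sum() == 0:
        raise ValueError("no events among positively weighted rows")
    if df["A"].nunique() < 2:
        raise ValueError("only one treatment arm carries positive weight")

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        # lifelines warns about non-integer weights; the sandwich variance we
        # report is exactly the remedy it suggests
        warnings.simplefilter("ignore", StatisticalWarning)
        cph.fit(df, duration_col="time", event_col="event", weights_col="w", robust=True)
        se_robust = float(cph.standard_errors_["A"])
        cph_model = CoxPHFitter()
        cph_model.fit(df, duration_col="time", event_col="event", weights_col="w", robust=False)
        se_model = float(cph_model.standard_errors_["A"])
    return CoxFit(
        log_hr=float(cph.params_["A"]),
        se_model=se_model,
        se_robust=se_robust,
        n=len(df),
        n_events=int(round(float((df["event"] > 0).sum()))),
        weighted=weighted,
        model_=cph,
        data_=df,
    )


def ph_test(fit: CoxFit) -> float:
    """Schoenfeld-residual test of the proportional-hazards assumption.

    Uses the Kaplan-Meier time transform (the cox.zph default).  Returns the
    p-value and stores it on the fit.
    """
    if fit.model_ is None or fit.data_ is None:
        raise ValueError("fit does not carry its model/data; refit with fit_weighted_cox")
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for a PH test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StatisticalWarning)
        res = proportional_hazard_test(fit.model_, fit.data_, time_transform="km")
    p = float(np.asarray(res.p_value).ravel()[0])
    fit.ph_pvalue = p
    return p


def km_weighted(time, event, A, weights=None) -> dict:
    """Weighted Kaplan-Meier curves per treatment arm.

    Returns {arm: {"curve": DataFrame(time, survival), "median": float}}.
    Scale-invariant in the weights.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=float),
            "A": np.asarray(A, dtype=float),
        }
    )
    w = np.ones(len(df)) if weights is None else np.asarray(
        getattr(weights, "values", weights), dtype=float
    )
    df["w"] = w
    df = df[df["w"] > 0]
    out = {}
    for arm, sub in df.groupby("A"):
        if len(sub) == 0:
            raise ValueError(f"arm {arm} is empty")
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StatisticalWarning)
            kmf.fit(sub["time"], event_observed=sub["event"], weights=sub["w"])
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        out[int(arm)] = {"curve": curve, "median": float(kmf.median_survival_time_)}
    return out


def plot_km(km: dict, ax=None, labels: dict | None = None):
    """Step plot of weighted Kaplan-Meier curves from :func:`km_weighted`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = labels or {}
    for arm, d in sorted(km.items()):
        c = d["curve"]
        ax.step(c["time"], c["survival"], where="post", label=labels.get(arm, f"A={arm}"))
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
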