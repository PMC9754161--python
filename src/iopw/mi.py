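"""Multiple imputation of covariates and Rubin's-rules pooling.

Strategy: covariates are imputed *before* any propensity score is derived
(impute-then-derive), and the entire weighting + outcome analysis is run
within each completed dataset before pooling (within-imputation analysis).
The imputation model pools covariate information from both cohorts and, for
original-cohort rows, brings in the treatment indicator and the outcome
(event indicator plus log event time, a standard proxy for the cumulative
hazard); target rows contribute covariate information only.

The chained-equations sampler uses predictive-mean matching for continuous
covariates and multinomial/logistic draws for categorical ones.  Parameter
uncertainty is propagated by refitting each component model on a bootstrap
resample of the observed rows at every update, a standard approximation to
drawing from the parameter posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputationStack", "impute_chained", "pool_rubin", "PooledHazardRatio"]

_PMM_DONORS = 5


@dataclass
class ImputationStack:
    """m completed copies of a cohort table, plus the trace that produced them."""

    m: int
    tables: list[pd.DataFrame]
    model_description: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m != len(self.tables):
            raise ValueError("m must equal the number of completed tables")

    def __iter__(self):
        return iter(self.tables)


def _predictor_frame(df: pd.DataFrame, covariates: dict[str, str], exclude: str) -> pd.DataFrame:
    """Numeric predictor matrix from current (filled) values of all other columns.

    Categorical covariates are one-hot encoded (reference level dropped).
    Cohort indicator S always enters; treatment/outcome columns enter as
    S * value so they are 0 (not missing) on target rows, with the S main
    effect absorbing the offset.
    """
    cols = {}
    for name, kind in covariates.items():
        if name == exclude:
            continue
        col = df[name]
        if kind == "categorical":
            d = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for dn in d:
                cols[dn] = d[dn]
        else:
            cols[name] = col.astype(float)
    if "S" in df.columns:
        s = df["S"].astype(float)
        cols["S"] = s
        for extra in ("A", "event"):
            if extra in df.columns:
                cols[f"S_{extra}"] = (s * df[extra].fillna(0.0)).astype(float)
        if "time" in df.columns:
            cols["S_logtime"] = (s * np.log1p(df["time"].fillna(0.0))).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "const", 1.0)
    return X


def _impute_continuous(y_obs, X_obs, X_mis, rng) -> np.ndarray:
    """Predictive-mean matching with a bootstrap parameter draw."""
    n = len(y_obs)
    boot = rng.integers(0, n, size=n)
    beta_b, *_ = np.linalg.lstsq(X_obs[boot], y_obs[boot], rcond=None)
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    pred_obs = X_obs @ beta  # observed matched on the MLE fit
    pred_mis = X_mis @ beta_b  # missing predicted under the drawn parameters
    out = np.empty(len(X_mis))
    k = min(_PMM_DONORS, n)
    for i, pm in enumerate(pred_mis):
        donors = np.argsort(np.abs(pred_obs - pm))[:k]
        out[i] = y_obs[donors[rng.integers(0, k)]]
    return out


def _impute_categorical(y_obs, X_obs, X_mis, rng) -> np.ndarray:
    """Multinomial (or logistic, K=2) draw with a bootstrap parameter draw."""
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(len(X_mis), classes[0])
    n = len(y_obs)
    for _ in range(10):  # bootstrap may drop a rare class; retry
        boot = rng.integers(0, n, size=n)
        if len(np.unique(y_obs[boot])) == len(classes):
            break
    else:
        boot = np.arange(n)
    # standardize predictors so the solver converges on raw-scale covariates
    mu = X_obs.mean(axis=0)
    sd = X_obs.std(axis=0)
    sd[sd == 0] = 1.0
    Xo = (X_obs - mu) / sd
    Xm = (X_mis - mu) / sd
    model = LogisticRegression(max_iter=1000, C=1e2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xo[boot], y_obs[boot])
        probs = model.predict_proba(Xm)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))[:, None]
    idx = (u > cum).sum(axis=1)
    return model.classes_[idx]


def impute_chained(
    cohort: pd.DataFrame,
    covariates: dict[str, str],
    m: int = 20,
    seed: int | None = None,
    n_burn: int = 10,
) -> ImputationStack:
    """Chained-equations multiple imputation of covariate cells.

    covariates maps column name -> kind in {continuous, binary, categorical}.
    Only covariate cells may be missing; id, S, A, time, event must be fully
    observed on the rows where they are defined and are never altered.
    Returns m completed tables; observed cells are identical across copies
    and to the input.  Deterministic given seed.
    """
    if m < 1:
        raise ValueError("need m >= 1 imputations")
    for name in covariates:
        if cohort[name].isna().all():
            raise ValueError(f"covariate {name!r} is 100% missing; cannot impute")
    miss_cols = [c for c in covariates if cohort[c].isna().any()]
    # visit order: least missing first, so early regressions see cleaner predictors
    miss_cols.sort(key=lambda c: cohort[c].isna().mean())
    masks = {c: cohort[c].isna().to_numpy() for c in miss_cols}

    streams = np.random.SeedSequence(0 if seed is None else seed).spawn(m)
    tables = []
    for chain in range(m):
        rng = np.random.default_rng(streams[chain])
        df = cohort.copy()
        # initialize missing cells with random draws from the observed marginal
        for c in miss_cols:
            obs_vals = cohort.loc[~masks[c], c].to_numpy()
            df.loc[masks[c], c] = rng.choice(obs_vals, size=masks[c].sum())
        n_sweeps = n_burn if miss_cols else 0
        for _ in range(n_sweeps):
            for c in miss_cols:
                kind = covariates[c]
                X = _predictor_frame(df, covariates, exclude=c).to_numpy(dtype=float)
                obs = ~masks[c]
                if kind == "continuous":
                    y_obs = cohort.loc[obs, c].to_numpy(dtype=float)
                    df.loc[masks[c], c] = _impute_continuous(y_obs, X[obs], X[masks[c]], rng)
                else:
                    y_obs = cohort.loc[obs, c].to_numpy()
                    drawn = _impute_categorical(y_obs, X[obs], X[masks[c]], rng)
                    df.loc[masks[c], c] = drawn
                    if kind == "binary":
                        df[c] = df[c].astype(float)
        tables.append(df)
    desc = {
        "imputed": miss_cols,
        "predictors": "all other covariates + S + S*A + S*event + S*log1p(time)",
        "n_burn": n_burn,
    }
    return ImputationStack(m=m, tables=tables, model_description=desc, seed=seed)


@dataclass
class PooledHazardRatio:
    """Rubin-pooled log hazard ratio with its variance decomposition."""

    log_hr: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int
    alpha: float = 0.05
    per_imputation: pd.DataFrame | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    @property
    def ci(self) -> tuple[float, float]:
        if np.isinf(self.df):
            q = stats.norm.ppf(1 - self.alpha / 2)
        else:
            q = stats.t.ppf(1 - self.alpha / 2, self.df)
        lo = self.log_hr - q * self.se
        hi = self.log_hr + q * self.se
        return (float(np.exp(lo)), float(np.exp(hi)))

    def __str__(self) -> str:
        lo, hi = self.ci
        return f"HR {self.hr:.2f} [{lo:.2f}, {hi:.2f}] (m={self.m})"


def pool_rubin(estimates, ses, alpha: float = 0.05, per_imputation: pd.DataFrame | None = None) -> PooledHazardRatio:
    """Pool per-imputation log hazard ratios by Rubin's rules.

    pooled = mean of estimates; within-variance = mean of squared SEs;
    between-variance = sample variance of estimates;
    total = within + (1 + 1/m) * between; degrees of freedom by the classic
    Rubin formula (normal reference when m = 1 or between-variance is 0).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size == 0 or est.shape != se.shape:
        raise ValueError("need m >= 1 estimates with matching SEs")
    if np.any(se <= 0):
        raise ValueError("all SEs must be positive")
    m = est.size
    pooled = float(est.mean())
    within = float(np.mean(se**2))
    between = float(est.var(ddof=1)) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    if m == 1 or between == 0:
        df = np.inf
    else:
        r = (1 + 1 / m) * between / within
        df = (m - 1) * (1 + 1 / r) ** 2
    return PooledHazardRatio(
        log_hr=pooled,
        within_var=within,
        between_var=between,
        total_var=total,
        df=float(df),
        m=m,
        alpha=alpha,
        per_imputation=per_imputation,
    )
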