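"""Propensity models and the two weighting steps.

Step 1 (confounding): a logistic regression of treatment A on confounders C,
fitted in the original cohort (S=1), gives P_i = P(A_i=1 | C_i); the
stabilized inverse-probability-of-treatment weight is

    W_i = A_i * P(A=1)/P_i + (1 - A_i) * P(A=0)/(1 - P_i).

Step 2 (transport): a logistic regression of cohort membership S on effect
modifiers E over the combined original+target rows gives
Q_i = P(S_i=1 | E_i); the composed inverse-odds-of-participation weight is

    V_i = W_i * (1 - Q_i)/Q_i * P(S=1)/P(S=0)   for S=1 rows,
    V_i = 0                                      for S=0 rows,

so the reweighted original cohort matches the target cohort's modifier
distribution while target rows carry no weight in the outcome model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SeparationError",
    "PSModelFit",
    "WeightVector",
    "design_matrix",
    "fit_treatment_ps",
    "fit_participation_ps",
    "stabilized_iptw",
    "iopw_compose",
    "truncate_weights",
]

_PROB_EPS = 1e-10


class SeparationError(RuntimeError):
    """Raised when a propensity model exhibits (quasi-)complete separation."""


@dataclass
class PSModelFit:
    """A fitted propensity model (treatment or participation)."""

    role: str  # "treatment" or "participation"
    params: pd.Series  # coefficients incl. intercept
    fitted: pd.Series  # P_i or Q_i, indexed like the input rows
    converged: bool
    formula: str

    def __post_init__(self) -> None:
        if self.role not in ("treatment", "participation"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class WeightVector:
    """Per-patient analysis weights with their provenance.

    step is "IPTW" (stabilized step-1 weights W) or "IOPW" (composed
    step-2 weights V).  `stabilizers` records the marginal constants used.
    """

    values: pd.Series
    step: str
    stabilizers: dict = field(default_factory=dict)
    truncated: bool = False
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.step not in ("IPTW", "IOPW"):
            raise ValueError(f"unknown weighting step {self.step!r}")
        if (self.values < 0).any():
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)


def design_matrix(data: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Main-effects design matrix: continuous columns linear, categorical as
    treatment-coded indicator contrasts (first level reference), plus a constant."""
    cols = {}
    for name in covariates:
        col = data[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values; impute first")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for dname in dummies:
                cols[dname] = dummies[dname]
        else:
            cols[name] = col.astype(float)
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


def _fit_logit(y: pd.Series, X: pd.DataFrame, role: str) -> PSModelFit:
    if y.nunique() != 2:
        raise ValueError(f"{role} outcome must have both levels present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
        except Exception as err:  # statsmodels raises on hard separation
            raise SeparationError(f"{role} model failed to fit: {err}") from err
    fitted = pd.Series(np.asarray(res.predict(X)), index=X.index)
    if ((fitted < _PROB_EPS) | (fitted > 1 - _PROB_EPS)).any():
        bad = fitted.index[(fitted < _PROB_EPS) | (fitted > 1 - _PROB_EPS)][:5].tolist()
        raise SeparationError(
            f"{role} model produced degenerate probabilities (separation); "
            f"first offending rows: {bad}"
        )
    converged = bool(res.mle_retvals.get("converged", True))
    formula = f"{role}: logit ~ " + " + ".join(c for c in X.columns if c != "const")
    return PSModelFit(role=role, params=res.params, fitted=fitted, converged=converged, formula=formula)


def fit_treatment_ps(
    cohort: pd.DataFrame,
    confounders: list[str],
    treatment: str = "A",
    cohort_col: str = "S",
) -> PSModelFit:
    """Fit the treatment propensity model P(A=1 | C) on original-cohort rows.

    Rows with S != 1 (if a cohort column is present) are excluded; the model
    is a main-effects logistic regression of the binary treatment on all
    confounders.
    """
    sub = cohort
    if cohort_col in cohort.columns:
        sub = cohort[cohort[cohort_col] == 1]
    if sub[treatment].isna().any():
        raise ValueError("treatment indicator contains missing values")
    X = design_matrix(sub, confounders)
    return _fit_logit(sub[treatment], X, role="treatment")


def fit_participation_ps(
    combined: pd.DataFrame,
    modifiers: list[str],
    cohort_col: str = "S",
) -> PSModelFit:
    """Fit the participation model Q = P(S=1 | E) on the combined cohorts."""
    s = combined[cohort_col]
    if set(pd.unique(s)) != {0, 1}:
        raise ValueError("combined table must contain both S=1 and S=0 rows")
    X = design_matrix(combined, modifiers)
    return _fit_logit(s, X, role="participation")


def stabilized_iptw(A, P, p_marginal: float | None = None) -> WeightVector:
    """Stabilized IPTW weights W_i from treatment A_i and fitted P_i.

    p_marginal defaults to the observed treated fraction mean(A).
    """
    A = pd.Series(A).astype(float)
    P = pd.Series(np.asarray(P, dtype=float), index=A.index)
    if len(A) != len(P):
        raise ValueError("A and P must have equal length")
    bad = P.index[(P <= 0) | (P >= 1)]
    if len(bad):
        raise ValueError(f"fitted probabilities outside (0,1) at rows {bad[:5].tolist()}")
    if p_marginal is None:
        p_marginal = float(A.mean())
    if not 0 < p_marginal < 1:
        raise ValueError("marginal treatment probability must lie in (0,1)")
    w = A * p_marginal / P + (1 - A) * (1 - p_marginal) / (1 - P)
    return WeightVector(
        values=w,
        step="IPTW",
        stabilizers={"p_treated": p_marginal, "p_control": 1 - p_marginal},
    )


def iopw_compose(
    W: WeightVector,
    Q,
    S,
    marginal_odds: float | None = None,
) -> WeightVector:
    """Compose step-2 weights V_i = W_i * (1-Q_i)/Q_i * P(S=1)/P(S=0).

    `W.values` must be indexed like the S=1 rows of the combined table;
    target rows (S=0) get weight 0.  marginal_odds defaults to n1/n2 from S.
    """
    if W.step != "IPTW":
        raise ValueError("step-2 composition requires step-1 IPTW weights")
    S = pd.Series(S).astype(int)
    Q = pd.Series(np.asarray(Q, dtype=float), index=S.index)
    n1 = int((S == 1).sum())
    n0 = int((S == 0).sum())
    if n0 == 0:
        raise ValueError("no target rows (S=0) in combined table")
    if marginal_odds is None:
        marginal_odds = n1 / n0
    if marginal_odds <= 0:
        raise ValueError("marginal odds must be positive")
    orig = S.index[S == 1]
    q1 = Q.loc[orig]
    bad = q1.index[(q1 <= 0) | (q1 >= 1)]
    if len(bad):
        raise ValueError(f"participation probabilities outside (0,1) at rows {bad[:5].tolist()}")
    v = pd.Series(0.0, index=S.index)
    v.loc[orig] = W.values.loc[orig] * (1 - q1) / q1 * marginal_odds
    return WeightVector(
        values=v,
        step="IOPW",
        stabilizers={**W.stabilizers, "marginal_odds": float(marginal_odds)},
    )


def truncate_weights(weights: WeightVector, lower_pct: float = 1.0, upper_pct: float = 99.0) -> WeightVector:
    """Symmetric percentile truncation of weights (off by default in pipelines).

    Percentiles are computed over strictly positive weights so step-2 zero
    weights on target rows stay zero.
    """
    pos = weights.values[weights.values > 0]
    lo, hi = np.percentile(pos, [lower_pct, upper_pct])
    clipped = weights.values.where(weights.values == 0, weights.values.clip(lo, hi))
    return WeightVector(
        values=clipped,
        step=weights.step,
        stabilizers=dict(weights.stabilizers),
        truncated=True,
        bounds=(float(lo), float(hi)),
    )
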