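"""Covariate-balance diagnostics: standardized mean differences and the Tipton index.

Standardized mean differences (SMD) quantify how far apart two groups'
covariate distributions sit on a scale-free footing; values above 0.1 are
conventionally flagged as meaningful imbalance.  Three variants are provided:
continuous (pooled-SD), binary (pooled binomial variance), and categorical
(multinomial Mahalanobis distance over K-1 category proportions, the
Yang–Dalton convention).  Weighted versions substitute weighted moments.

The Tipton index summarizes the overlap of two propensity-score
distributions as the Bhattacharyya coefficient of their kernel-density
estimates; it lies in [0, 1], with values above 0.8 conventionally read as
"similar enough to reweight credibly".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import gaussian_kde

__all__ = [
    "smd_continuous",
    "smd_binary",
    "smd_categorical",
    "weighted_smd",
    "tipton_index",
    "balance_table",
    "summarize_balance",
    "BalanceReport",
]


def smd_continuous(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """SMD for a continuous covariate: |mean_b - mean_a| / sqrt((sd_a^2 + sd_b^2)/2)."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    denom = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if denom == 0:
        if mean_a == mean_b:
            return 0.0
        raise ValueError("SMD undefined: both SDs are zero with unequal means")
    return float(abs(mean_b - mean_a) / denom)


def smd_binary(p_a: float, p_b: float) -> float:
    """SMD for a binary covariate from the two group proportions."""
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    denom = np.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
    if denom == 0:
        if p_a == p_b:
            return 0.0
        raise ValueError("SMD undefined: degenerate proportions with unequal values")
    return float(abs(p_b - p_a) / denom)


def smd_categorical(props_a, props_b) -> float:
    """Multinomial Mahalanobis SMD over K >= 2 category proportions.

    d = sqrt(T' S^{-1} T) with T the difference of the last K-1 category
    proportions and S the average of the two multinomial covariance matrices.
    Zero-frequency categories (in both groups) are dropped before inversion.
    Reduces to :func:`smd_binary` when K = 2.
    """
    a = np.asarray(props_a, dtype=float)
    b = np.asarray(props_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two proportion vectors of equal length K >= 2")
    for v in (a, b):
        if not np.isclose(v.sum(), 1.0, atol=1e-8):
            raise ValueError("proportion vectors must sum to 1")
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    if a.size < 2:
        return 0.0
    # drop the first category; the multinomial constraint makes it redundant
    T = (b - a)[1:]
    cov_a = np.diag(a[1:]) - np.outer(a[1:], a[1:])
    cov_b = np.diag(b[1:]) - np.outer(b[1:], b[1:])
    S = (cov_a + cov_b) / 2.0
    try:
        sol = np.linalg.solve(S, T)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular multinomial covariance; SMD undefined") from err
    return float(np.sqrt(max(T @ sol, 0.0)))


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _wvar(x: np.ndarray, w: np.ndarray) -> float:
    m = _wmean(x, w)
    return float(np.sum(w * (x - m) ** 2) / np.sum(w))


def weighted_smd(values, group, weights=None, kind: str = "continuous") -> float:
    """Weighted SMD between the two levels of `group`.

    Weighted moments use normalized weights within each group; with unit
    weights this equals the unweighted SMD.  Missing values (NaN) are
    excluded; categorical/binary proportions are computed over non-missing
    cells only.
    """
    values = pd.Series(np.asarray(values, dtype=object))
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels.size}")
    if weights is None:
        weights = np.ones(len(values))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")

    obs = values.notna().to_numpy()
    stats = []
    for lev in levels:
        mask = (group == lev) & obs
        w = weights[mask]
        if w.sum() <= 0:
            raise ValueError(f"group {lev!r} has zero total weight")
        x = values[mask]
        stats.append((x, w))

    if kind == "continuous":
        (xa, wa), (xb, wb) = stats
        xa = xa.astype(float).to_numpy()
        xb = xb.astype(float).to_numpy()
        return smd_continuous(
            _wmean(xa, wa), np.sqrt(_wvar(xa, wa)), _wmean(xb, wb), np.sqrt(_wvar(xb, wb))
        )
    if kind == "binary":
        (xa, wa), (xb, wb) = stats
        return smd_binary(
            _wmean(xa.astype(float).to_numpy(), wa),
            _wmean(xb.astype(float).to_numpy(), wb),
        )
    if kind == "categorical":
        cats = sorted(pd.unique(values[obs]))
        props = []
        for x, w in stats:
            p = np.array([w[(x == c).to_numpy()].sum() for c in cats]) / w.sum()
            props.append(p)
        return smd_categorical(props[0], props[1])
    raise ValueError(f"unknown covariate kind {kind!r}")


def tipton_index(
    ps_original,
    ps_target,
    scale: str = "logit",
    grid_size: int = 512,
) -> float:
    """Similarity of two propensity-score distributions in [0, 1].

    Computed as the Bhattacharyya coefficient integral sqrt(f1 * f2) of
    Gaussian kernel-density estimates (Silverman bandwidth) of the two score
    distributions, numerically integrated on a common grid.  `scale="logit"`
    (default) transforms scores off the bounded (0, 1) interval before
    density estimation; `scale="probability"` estimates densities on the raw
    scores.  1 means identical distributions, 0 means disjoint support.
    """
    p1 = np.asarray(ps_original, dtype=float)
    p2 = np.asarray(ps_target, dtype=float)
    if p1.size < 2 or p2.size < 2:
        raise ValueError("need at least 2 propensity scores per cohort")
    for v in (p1, p2):
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError("propensity scores must lie strictly in (0, 1)")
    if scale == "logit":
        x1, x2 = logit(p1), logit(p2)
    elif scale == "probability":
        x1, x2 = p1, p2
    else:
        raise ValueError(f"unknown scale {scale!r}")

    k1 = gaussian_kde(x1, bw_method="silverman")
    k2 = gaussian_kde(x2, bw_method="silverman")
    pad = 4.0 * max(np.sqrt(k1.covariance[0, 0]), np.sqrt(k2.covariance[0, 0]))
    lo = min(x1.min(), x2.min()) - pad
    hi = max(x1.max(), x2.max()) + pad
    grid = np.linspace(lo, hi, grid_size)
    f1 = np.clip(k1(grid), 0, None)
    f2 = np.clip(k2(grid), 0, None)
    bc = float(np.trapezoid(np.sqrt(f1 * f2), grid))
    return float(min(bc, 1.0))


def balance_table(
    data: pd.DataFrame,
    covariates: dict[str, str],
    group: str,
    weights=None,
) -> pd.DataFrame:
    """Per-covariate unweighted and weighted SMD between the two `group` levels.

    `covariates` maps column name -> kind in {continuous, binary, categorical}.
    Returns a DataFrame with columns covariate, kind, smd_unweighted,
    smd_weighted (NaN when no weights given).
    """
    rows = []
    for name, kind in covariates.items():
        smd0 = weighted_smd(data[name], data[group], None, kind)
        smd1 = (
            weighted_smd(data[name], data[group], weights, kind)
            if weights is not None
            else np.nan
        )
        rows.append({"covariate": name, "kind": kind, "smd_unweighted": smd0, "smd_weighted": smd1})
    return pd.DataFrame(rows)


def summarize_balance(tables: list[pd.DataFrame], threshold: float = 0.1) -> pd.DataFrame:
    """Summarize per-imputation balance tables as median (min, max) across imputations."""
    stacked = pd.concat(tables, keys=range(len(tables)), names=["imputation", None])
    g = stacked.groupby("covariate", sort=False)
    out = pd.DataFrame(
        {
            "kind": g["kind"].first(),
            "smd_unweighted_median": g["smd_unweighted"].median(),
            "smd_weighted_median": g["smd_weighted"].median(),
            "smd_weighted_min": g["smd_weighted"].min(),
            "smd_weighted_max": g["smd_weighted"].max(),
        }
    ).reset_index()
    out["flag"] = out["smd_weighted_median"] > threshold
    return out


@dataclass
class BalanceReport:
    """Balance diagnostics summarized across imputations.

    table : per-covariate SMD summary (median and range of the weighted SMD
        across imputations, plus the median unweighted SMD).
    tipton_mean, tipton_sd : Tipton index mean +/- SD across imputations
        (participation step only; None for the treatment step).
    threshold : SMD flagging threshold.
    per_imputation : raw per-imputation balance tables, retained for audit.
    """

    table: pd.DataFrame
    tipton_mean: float | None = None
    tipton_sd: float | None = None
    threshold: float = 0.1
    per_imputation: list[pd.DataFrame] = field(default_factory=list)

    @property
    def all_balanced(self) -> bool:
        return bool((self.table["smd_weighted_median"] <= self.threshold).all())
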