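"""End-to-end two-step weighted analysis over an imputation stack.

Step 1 (confounding): within each completed dataset, fit the treatment
propensity model on original-cohort rows, build stabilized IPTW weights,
check covariate balance, and fit the weighted treatment-only Cox model with
robust variance; pool log hazard ratios across imputations by Rubin's rules.

Step 2 (transport): within each completed dataset, additionally fit the
participation model on the combined cohorts, compose the inverse odds of
participation weights V = W * (1-Q)/Q * P(S=1)/P(S=0), compute the Tipton
similarity index between the two cohorts' participation-score distributions,
check effect-modifier balance of the V-weighted original cohort against the
(unweighted) target cohort, and fit the V-weighted Cox model on
original-cohort rows only.

The `TwoStepWeightedCox` model class wraps imputation + both steps behind a
statsmodels-style fit() returning a results object with a summary() table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import BalanceReport, balance_table, summarize_balance, tipton_index
from .mi import ImputationStack, PooledHazardRatio, impute_chained, pool_rubin
from .survival import fit_weighted_cox, ph_test
from .weights import (
    WeightVector,
    fit_participation_ps,
    fit_treatment_ps,
    iopw_compose,
    stabilized_iptw,
    truncate_weights,
)

__all__ = ["run_step1", "run_step2", "TwoStepWeightedCox", "TwoStepWeightedCoxResults"]

logger = logging.getLogger("iopw")


def _ess(w: np.ndarray) -> float:
    """Kish effective sample size of a weight vector."""
    w = w[w > 0]
    return float(w.sum() ** 2 / np.sum(w**2))


def _step1_weights(table: pd.DataFrame, confounders: list[str], truncate) -> WeightVector:
    ps = fit_treatment_ps(table, confounders)
    orig = table[table["S"] == 1] if "S" in table.columns else table
    w = stabilized_iptw(orig["A"], ps.fitted)
    if truncate:
        w = truncate_weights(w, *truncate)
    return w


def run_step1(
    stack: ImputationStack,
    confounders: dict[str, str],
    truncate: tuple[float, float] | None = None,
    compute_ph: bool = True,
    smd_threshold: float = 0.1,
) -> tuple[PooledHazardRatio, BalanceReport]:
    """IPTW analysis within each imputed dataset, Rubin-pooled.

    confounders maps covariate name -> kind in {continuous, binary, categorical}.
    """
    names = list(confounders)
    rows, balances = [], []
    for k, table in enumerate(stack):
        orig = table[table["S"] == 1].reset_index(drop=True) if "S" in table.columns else table
        w = _step1_weights(orig, names, truncate)
        bal = balance_table(orig, confounders, group="A", weights=w.values.to_numpy())
        fit = fit_weighted_cox(orig["time"], orig["event"], orig["A"], w)
        p_ph = ph_test(fit) if compute_ph else np.nan
        logger.info(
            "step1 imputation=%d n=%d ess=%.1f loghr=%.4f", k, fit.n, _ess(w.values.to_numpy()), fit.log_hr
        )
        rows.append(
            {
                "imputation": k,
                "log_hr": fit.log_hr,
                "se_robust": fit.se_robust,
                "ph_pvalue": p_ph,
                "n": fit.n,
                "n_events": fit.n_events,
                "ess": _ess(w.values.to_numpy()),
                "mean_weight": float(w.values.mean()),
            }
        )
        balances.append(bal)
    per_imp = pd.DataFrame(rows)
    pooled = pool_rubin(per_imp["log_hr"], per_imp["se_robust"], per_imputation=per_imp)
    report = BalanceReport(
        table=summarize_balance(balances, smd_threshold),
        threshold=smd_threshold,
        per_imputation=balances,
    )
    return pooled, report


def run_step2(
    stack: ImputationStack,
    modifiers: dict[str, str],
    confounders: dict[str, str] | None = None,
    truncate: tuple[float, float] | None = None,
    compute_ph: bool = True,
    smd_threshold: float = 0.1,
    tipton_scale: str = "logit",
) -> tuple[PooledHazardRatio, BalanceReport]:
    """IPTW + IOPW transport analysis within each imputed dataset, Rubin-pooled.

    Step-1 weights are recomputed inside each completed dataset (confounders
    default to the effect modifiers, matching the design where the same
    covariates play both roles).
    """
    names = list(modifiers)
    conf = confounders or modifiers
    rows, balances, tiptons = [], [], []
    for k, table in enumerate(stack):
        if not (table["S"] == 0).any():
            raise ValueError("step 2 requires target-cohort rows (S=0)")
        combined = table.reset_index(drop=True)
        orig_mask = combined["S"] == 1
        w1 = _step1_weights(combined, list(conf), truncate)
        q = fit_participation_ps(combined, names)
        # align step-1 weights (defined on S=1 rows) onto the combined index
        w_full = pd.Series(0.0, index=combined.index)
        w_full.loc[orig_mask] = w1.values.to_numpy()
        w1_aligned = WeightVector(values=w_full, step="IPTW", stabilizers=w1.stabilizers)
        v = iopw_compose(w1_aligned, q.fitted, combined["S"])
        tip = tipton_index(
            q.fitted[orig_mask].to_numpy(), q.fitted[~orig_mask].to_numpy(), scale=tipton_scale
        )
        # V-weighted original cohort vs unweighted target cohort
        bal_w = v.values.where(combined["S"] == 1, 1.0).to_numpy()
        bal = balance_table(combined, modifiers, group="S", weights=bal_w)
        orig = combined[orig_mask]
        fit = fit_weighted_cox(orig["time"], orig["event"], orig["A"], v.values[orig_mask])
        p_ph = ph_test(fit) if compute_ph else np.nan
        logger.info(
            "step2 imputation=%d n=%d ess=%.1f tipton=%.3f loghr=%.4f",
            k, fit.n, _ess(v.values.to_numpy()), tip, fit.log_hr,
        )
        rows.append(
            {
                "imputation": k,
                "log_hr": fit.log_hr,
                "se_robust": fit.se_robust,
                "ph_pvalue": p_ph,
                "n": fit.n,
                "n_events": fit.n_events,
                "ess": _ess(v.values.to_numpy()),
                "tipton": tip,
            }
        )
        balances.append(bal)
        tiptons.append(tip)
    per_imp = pd.DataFrame(rows)
    pooled = pool_rubin(per_imp["log_hr"], per_imp["se_robust"], per_imputation=per_imp)
    report = BalanceReport(
        table=summarize_balance(balances, smd_threshold),
        tipton_mean=float(np.mean(tiptons)),
        tipton_sd=float(np.std(tiptons, ddof=1)) if len(tiptons) > 1 else 0.0,
        threshold=smd_threshold,
        per_imputation=balances,
    )
    return pooled, report


class TwoStepWeightedCox:
    """Two-step weighted hazard-ratio model for a combined two-cohort table.

    Parameters
    ----------
    data : DataFrame with columns S (1 = original cohort with treatment and
        outcome, 0 = target cohort with covariates only), A, time, event, and
        the covariates.
    covariates : mapping of covariate name -> kind in
        {continuous, binary, categorical}; used as confounders in step 1 and
        effect modifiers in step 2.
    m : number of imputations when covariates have missing cells (a single
        copy is analyzed when the data are complete).
    truncate : optional (lower, upper) weight-truncation percentiles.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: dict[str, str],
        m: int = 20,
        truncate: tuple[float, float] | None = None,
        smd_threshold: float = 0.1,
        tipton_scale: str = "logit",
    ):
        required = {"S", "A", "time", "event"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required columns {sorted(missing)}")
        unknown = set(covariates) - set(data.columns)
        if unknown:
            raise ValueError(f"covariates not in data: {sorted(unknown)}")
        self.data = data.reset_index(drop=True)
        self.covariates = dict(covariates)
        self.m = m
        self.truncate = truncate
        self.smd_threshold = smd_threshold
        self.tipton_scale = tipton_scale

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, covariates: dict[str, str], **kwargs) -> "TwoStepWeightedCox":
        return cls(data, covariates, **kwargs)

    def fit(self, seed: int | None = None, steps: tuple[int, ...] = (1, 2)) -> "TwoStepWeightedCoxResults":
        """Impute (if needed), run the requested steps, and pool."""
        has_missing = any(self.data[c].isna().any() for c in self.covariates)
        if has_missing:
            stack = impute_chained(self.data, self.covariates, m=self.m, seed=seed)
        else:
            stack = ImputationStack(m=1, tables=[self.data], seed=seed)
        step1 = step2 = None
        if 1 in steps:
            step1 = run_step1(
                stack, self.covariates, truncate=self.truncate, smd_threshold=self.smd_threshold
            )
        if 2 in steps and (self.data["S"] == 0).any():
            step2 = run_step2(
                stack,
                self.covariates,
                truncate=self.truncate,
                smd_threshold=self.smd_threshold,
                tipton_scale=self.tipton_scale,
            )
        return TwoStepWeightedCoxResults(self, stack, step1, step2, seed)


@dataclass
class TwoStepWeightedCoxResults:
    """Results of the two-step analysis: pooled HRs, balance, similarity."""

    model: TwoStepWeightedCox
    stack: ImputationStack
    _step1: tuple[PooledHazardRatio, BalanceReport] | None
    _step2: tuple[PooledHazardRatio, BalanceReport] | None
    seed: int | None

    @property
    def step1_hr(self) -> PooledHazardRatio:
        return self._step1[0]

    @property
    def step1_balance(self) -> BalanceReport:
        return self._step1[1]

    @property
    def step2_hr(self) -> PooledHazardRatio:
        return self._step2[0]

    @property
    def step2_balance(self) -> BalanceReport:
        return self._step2[1]

    @property
    def tipton(self) -> tuple[float, float] | None:
        if self._step2 is None:
            return None
        return (self._step2[1].tipton_mean, self._step2[1].tipton_sd)

    def provenance(self) -> dict:
        cfg = {
            "covariates": self.model.covariates,
            "m": self.stack.m,
            "seed": self.seed,
            "truncate": self.model.truncate,
        }
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        return {**cfg, "config_hash": digest}

    def summary(self) -> str:
        lines = ["Two-step weighted Cox analysis", "=" * 34]
        if self._step1 is not None:
            hr, bal = self._step1
            lo, hi = hr.ci
            pi = hr.per_imputation
            lines += [
                f"Step 1 (IPTW, confounding): HR {hr.hr:.2f} [{lo:.2f}, {hi:.2f}]  m={hr.m}",
                f"  events (median across imputations): {int(pi['n_events'].median())}",
                f"  PH test p median (min, max): {pi['ph_pvalue'].median():.4f} "
                f"({pi['ph_pvalue'].min():.4f}, {pi['ph_pvalue'].max():.4f})",
                f"  max weighted SMD (median across imputations): "
                f"{bal.table['smd_weighted_median'].max():.3f} "
                f"({'all below' if bal.all_balanced else 'SOME ABOVE'} {bal.threshold})",
            ]
        if self._step2 is not None:
            hr, bal = self._step2
            lo, hi = hr.ci
            pi = hr.per_imputation
            lines += [
                f"Step 2 (IOPW, transport):   HR {hr.hr:.2f} [{lo:.2f}, {hi:.2f}]  m={hr.m}",
                f"  Tipton index mean (SD): {bal.tipton_mean:.2f} ({bal.tipton_sd:.2f})",
                f"  PH test p median (min, max): {pi['ph_pvalue'].median():.4f} "
                f"({pi['ph_pvalue'].min():.4f}, {pi['ph_pvalue'].max():.4f})",
                f"  max weighted SMD (median across imputations): "
                f"{bal.table['smd_weighted_median'].max():.3f} "
                f"({'all below' if bal.all_balanced else 'SOME ABOVE'} {bal.threshold})",
            ]
        return "\n".join(lines)

    def report_markdown(self) -> str:
        """Markdown report mirroring the balance-table + HR-line layout."""
        parts = ["# Two-step weighted analysis report", ""]
        parts.append("```\n" + self.summary() + "\n```")
        for label, blk in (("Step 1", self._step1), ("Step 2", self._step2)):
            if blk is None:
                continue
            parts += ["", f"## {label} balance", "", blk[1].table.to_markdown(index=False)]
        prov = self.provenance()
        parts += ["", f"_config hash: `{prov['config_hash'][:16]}`, seed: {prov['seed']}_", ""]
        return "\n".join(parts)
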