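"""Synthetic original/target cohort generator with known ground truth.

The generator realizes the causal structure the two-step analysis is built
for: baseline covariates C confound a binary treatment A (C -> A, C -> Y), a
subset of covariates E modify the treatment effect (A x E -> Y), and the same
modifiers drive selection into the original cohort (E -> S).  Event times are
right-censored draws from an exponential (default) or Weibull proportional
hazards model, so the conditional treatment hazard ratio exp(beta_A) and all
interaction terms are known exactly, and the *marginal* hazard ratio in either
population can be computed by a counterfactual Monte-Carlo oracle.

Two generation modes:

* per-cohort marginals (default, ``selection_model=None``): exactly
  ``n_original`` S=1 rows and ``n_target`` S=0 rows, covariates drawn from
  cohort-specific marginal distributions;
* explicit selection model: covariates for a pool of
  ``n_original + n_target`` rows are drawn from the base (``original``)
  marginals and S is Bernoulli(expit(selection linear predictor)), so a
  logistic refit of S on E recovers the selection coefficients; realized
  cohort sizes are then binomial around their expectations.

Randomness is split into named substreams (covariates, selection, assignment,
outcome, censoring, missingness) off a single seed, so stages replay
independently and output is byte-identical for a given config + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CovariateSpec",
    "MissingnessSpec",
    "SimulationConfig",
    "SimulationTruth",
    "generate_cohorts",
    "impose_missingness",
    "oracle_marginal_hr",
    "table_like_config",
]

_SUBSTREAMS = ("covariates", "selection", "assignment", "outcome", "censoring", "missingness")


@dataclass
class CovariateSpec:
    """Marginal distribution of one baseline covariate, per cohort.

    kind: "continuous" (params {mean, sd}), "binary" ({p}) or "categorical"
    ({probs} over `levels`).  `target` defaults to `original` when omitted,
    i.e. no distributional shift for that covariate.
    """

    name: str
    kind: str
    original: dict
    target: dict | None = None
    levels: list[str] | None = None

    def params(self, population: str) -> dict:
        if population == "target" and self.target is not None:
            return self.target
        return self.original

    def validate(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        for pop in ("original", "target"):
            p = self.params(pop)
            if self.kind == "continuous":
                if p.get("sd", 0) <= 0:
                    raise ValueError(f"{self.name}: sd must be positive")
            elif self.kind == "binary":
                if not 0 <= p.get("p", -1) <= 1:
                    raise ValueError(f"{self.name}: p must lie in [0,1]")
            else:
                if self.levels is None or len(self.levels) < 2:
                    raise ValueError(f"{self.name}: categorical needs >= 2 levels")
                probs = np.asarray(p.get("probs", []), dtype=float)
                if len(probs) != len(self.levels) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-8):
                    raise ValueError(f"{self.name}: probs must match levels and sum to 1")

    def draw(self, n: int, rng: np.random.Generator, population: str):
        p = self.params(population)
        if self.kind == "continuous":
            return rng.normal(p["mean"], p["sd"], size=n)
        if self.kind == "binary":
            return rng.binomial(1, p["p"], size=n).astype(float)
        return rng.choice(np.array(self.levels, dtype=object), size=n, p=p["probs"])


@dataclass
class MissingnessSpec:
    """Missingness mechanism for one covariate.

    Either MCAR with a single `rate`, or MAR with `depends_on` naming a fully
    observed column and `rates` mapping its levels to missingness rates
    (optional "default" key for unlisted levels; rows where the conditioning
    column is itself undefined, e.g. treatment on target rows, fall back to
    "default", else 0).
    """

    name: str
    rate: float | None = None
    depends_on: str | None = None
    rates: dict | None = None

    def validate(self) -> None:
        if self.depends_on is None:
            if self.rate is None or not 0 <= self.rate < 1:
                raise ValueError(f"{self.name}: MCAR rate must lie in [0,1)")
        else:
            if not self.rates:
                raise ValueError(f"{self.name}: MAR spec needs a rates mapping")
            for r in self.rates.values():
                if not 0 <= r < 1:
                    raise ValueError(f"{self.name}: MAR rates must lie in [0,1)")


@dataclass
class SimulationConfig:
    """Full generative specification for a combined original/target cohort."""

    n_original: int
    n_target: int
    covariates: list[CovariateSpec]
    treatment_model: dict  # {"intercept": float, "coef": {name: float | {level: float}}}
    outcome_model: dict  # {"baseline", "lambda0", "shape", "treatment", "coef", "interactions"}
    selection_model: dict | None = None  # {"intercept", "coef"} -> Bernoulli selection mode
    censoring: dict = field(default_factory=lambda: {"horizon": 1095.0, "rate": 0.0})
    missingness: list[MissingnessSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_original < 2 or self.n_target < 0:
            raise ValueError("need n_original >= 2 and n_target >= 0")
        if not self.covariates:
            raise ValueError("need at least one covariate")
        for cv in self.covariates:
            cv.validate()
        om = self.outcome_model
        if om.get("lambda0", 0) <= 0 or om.get("shape", 1.0) <= 0:
            raise ValueError("baseline hazard parameters must be positive")
        if om.get("baseline", "exponential") not in ("exponential", "weibull"):
            raise ValueError("baseline must be 'exponential' or 'weibull'")
        if self.censoring.get("horizon", 0) <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.censoring.get("rate", 0.0) < 0:
            raise ValueError("censoring rate must be nonnegative")
        names = {cv.name for cv in self.covariates}
        with_missing = {ms.name for ms in self.missingness}
        for ms in self.missingness:
            ms.validate()
            if ms.name not in names:
                raise ValueError(f"missingness on unknown covariate {ms.name!r}")
            if ms.depends_on is not None and ms.depends_on in with_missing:
                raise ValueError(
                    f"{ms.name}: MAR dependence on {ms.depends_on!r}, which itself has "
                    "missingness; mechanism would not be verifiable"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        """Build a config from a plain (YAML/JSON-loaded) mapping."""
        d = dict(d)
        d["covariates"] = [
            cv if isinstance(cv, CovariateSpec) else CovariateSpec(**cv)
            for cv in d.get("covariates", [])
        ]
        d["missingness"] = [
            ms if isinstance(ms, MissingnessSpec) else MissingnessSpec(**ms)
            for ms in d.get("missingness", [])
        ]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def covariate_kinds(self) -> dict[str, str]:
        """Mapping covariate name -> kind, as the analysis modules expect."""
        return {cv.name: cv.kind for cv in self.covariates}

    def spec_for(self, name: str) -> CovariateSpec:
        for cv in self.covariates:
            if cv.name == name:
                return cv
        raise KeyError(name)

    def rng(self, stream: str, seed: int | None = None) -> np.random.Generator:
        if stream not in _SUBSTREAMS:
            raise KeyError(stream)
        base = self.seed if seed is None else seed
        ss = np.random.SeedSequence(base).spawn(len(_SUBSTREAMS))
        return np.random.default_rng(ss[_SUBSTREAMS.index(stream)])


@dataclass
class SimulationTruth:
    """The generating coefficients plus (optionally) oracle marginal HRs."""

    config: SimulationConfig
    beta_treatment: float
    interactions: dict
    true_conditional_hr: float
    oracle_marginal_hr_original: float | None = None
    oracle_marginal_hr_target: float | None = None

    def to_dict(self) -> dict:
        d = {
            "beta_treatment": self.beta_treatment,
            "interactions": self.interactions,
            "true_conditional_hr": self.true_conditional_hr,
            "oracle_marginal_hr_original": self.oracle_marginal_hr_original,
            "oracle_marginal_hr_target": self.oracle_marginal_hr_target,
            "config": asdict(self.config),
        }
        return d


def _linear_predictor(df: pd.DataFrame, coef: dict) -> np.ndarray:
    """Sum coefficient contributions over raw covariate columns.

    Continuous/binary coefficients multiply the column; categorical
    coefficients are {level: value} lookups (unlisted levels contribute 0).
    """
    lp = np.zeros(len(df))
    for name, c in (coef or {}).items():
        col = df[name]
        if isinstance(c, dict):
            lp += col.map(lambda v: c.get(v, 0.0)).to_numpy(dtype=float)
        else:
            lp += c * col.to_numpy(dtype=float)
    return lp


def _draw_covariates(config: SimulationConfig, n: int, rng: np.random.Generator, population: str) -> pd.DataFrame:
    return pd.DataFrame(
        {cv.name: cv.draw(n, rng, population) for cv in config.covariates}
    )


def _event_times(config: SimulationConfig, lp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform draw from H(t) = lambda0 * t^shape * exp(lp)."""
    om = config.outcome_model
    lam0 = om["lambda0"]
    shape = om.get("shape", 1.0)
    e = rng.exponential(1.0, size=len(lp))
    t = (e / (lam0 * np.exp(lp))) ** (1.0 / shape)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("hazard parameters produced non-finite or non-positive event times")
    return t


def _outcome_lp(config: SimulationConfig, cov: pd.DataFrame, A: np.ndarray) -> np.ndarray:
    om = config.outcome_model
    lp = _linear_predictor(cov, om.get("coef", {}))
    lp = lp + om.get("treatment", 0.0) * A
    inter = om.get("interactions", {})
    if inter:
        lp = lp + A * _linear_predictor(cov, inter)
    return lp


def generate_cohorts(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the combined cohort table and its ground truth.

    Returns a DataFrame with columns id, S, the covariates, and A/time/event
    (NaN on target rows), and a SimulationTruth carrying the generating
    coefficients.  Deterministic given config + seed (seed defaults to
    config.seed).
    """
    config.validate()
    cov_rng = config.rng("covariates", seed)

    if config.selection_model is None:
        cov1 = _draw_covariates(config, config.n_original, cov_rng, "original")
        cov0 = _draw_covariates(config, config.n_target, cov_rng, "target")
        S = np.concatenate([np.ones(len(cov1)), np.zeros(len(cov0))]).astype(int)
        cov = pd.concat([cov1, cov0], ignore_index=True)
    else:
        n_pool = config.n_original + config.n_target
        cov = _draw_covariates(config, n_pool, cov_rng, "original")
        sel = config.selection_model
        p_sel = expit(sel.get("intercept", 0.0) + _linear_predictor(cov, sel.get("coef", {})))
        sel_rng = config.rng("selection", seed)
        S = sel_rng.binomial(1, p_sel)
        if S.sum() < 2 or (1 - S).sum() < 1:
            raise ValueError("selection model produced a degenerate cohort split")

    df = cov.copy()
    df.insert(0, "S", S)
    df.insert(0, "id", np.arange(len(df)))

    orig = df["S"] == 1
    tm = config.treatment_model
    p_a = expit(tm.get("intercept", 0.0) + _linear_predictor(df.loc[orig], tm.get("coef", {})))
    a_rng = config.rng("assignment", seed)
    A = a_rng.binomial(1, p_a).astype(float)

    lp = _outcome_lp(config, df.loc[orig], A)
    o_rng = config.rng("outcome", seed)
    T = _event_times(config, lp, o_rng)

    c_rng = config.rng("censoring", seed)
    horizon = float(config.censoring.get("horizon", 1095.0))
    C = np.full(len(T), horizon)
    rate = float(config.censoring.get("rate", 0.0))
    if rate > 0:
        C = np.minimum(C, c_rng.exponential(1.0 / rate, size=len(T)))
    time = np.minimum(T, C)
    event = (T <= C).astype(float)

    df["A"] = np.nan
    df["time"] = np.nan
    df["event"] = np.nan
    df.loc[orig, "A"] = A
    df.loc[orig, "time"] = time
    df.loc[orig, "event"] = event

    om = config.outcome_model
    truth = SimulationTruth(
        config=config,
        beta_treatment=float(om.get("treatment", 0.0)),
        interactions=dict(om.get("interactions", {})),
        true_conditional_hr=float(np.exp(om.get("treatment", 0.0))),
    )
    return df, truth


def impose_missingness(
    cohort: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Blank covariate cells according to the configured MCAR/MAR mechanisms.

    Only covariate columns are ever blanked; id, S, A, time and event are
    untouched.  Missing cells are NaN.  Deterministic given config + seed.
    """
    config.validate()
    rng = config.rng("missingness", seed)
    out = cohort.copy()
    for ms in config.missingness:
        if ms.depends_on is None:
            p = np.full(len(out), ms.rate)
        else:
            cond = out[ms.depends_on]
            default = ms.rates.get("default", 0.0)
            p = np.array(
                [
                    ms.rates.get(v, ms.rates.get(str(v), default)) if pd.notna(v) else default
                    for v in cond
                ],
                dtype=float,
            )
        mask = rng.random(len(out)) < p
        col = out[ms.name]
        if col.dtype == object:
            out.loc[mask, ms.name] = None
            out[ms.name] = out[ms.name].where(out[ms.name].notna(), np.nan)
        else:
            out.loc[mask, ms.name] = np.nan
    return out


def oracle_marginal_hr(
    truth: SimulationTruth,
    population: str = "original",
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo counterfactual marginal hazard ratio in a population.

    Draws `n_mc` covariate vectors from the population's distribution, sets
    A=1 and A=0 for every draw, simulates both uncensored potential event
    times, and returns the hazard ratio from a treatment-only Cox fit on the
    stacked counterfactual data.  This marginal HR is the estimand the
    weighted analyses target (it has no closed form once covariates affect
    the hazard, because the Cox HR is non-collapsible).
    """
    from lifelines import CoxPHFitter

    if population not in ("original", "target"):
        raise ValueError("population must be 'original' or 'target'")
    config = truth.config
    rng = np.random.default_rng(seed)

    if config.selection_model is None:
        cov = _draw_covariates(config, n_mc, rng, population)
    else:
        # base covariates conditioned on the realized selection indicator
        sel = config.selection_model
        keep_frames, kept = [], 0
        while kept < n_mc:
            block = _draw_covariates(config, max(n_mc, 10_000), rng, "original")
            p = expit(sel.get("intercept", 0.0) + _linear_predictor(block, sel.get("coef", {})))
            accept = rng.random(len(block)) < (p if population == "original" else 1 - p)
            sub = block[accept]
            keep_frames.append(sub)
            kept += len(sub)
        cov = pd.concat(keep_frames, ignore_index=True).iloc[:n_mc]

    frames = []
    for a in (1.0, 0.0):
        lp = _outcome_lp(config, cov, np.full(n_mc, a))
        t = _event_times(config, lp, rng)
        frames.append(pd.DataFrame({"time": t, "event": 1.0, "A": a}))
    stacked = pd.concat(frames, ignore_index=True)
    cph = CoxPHFitter()
    cph.fit(stacked, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["A"]))


def table_like_config(
    n_original: int = 752,
    n_target: int = 3109,
    seed: int = 0,
    missingness: bool = True,
) -> SimulationConfig:
    """A default configuration emulating the structure of a real-world
    two-cohort oncology dataset: Normal age, multinomial race/stage/ECOG,
    binary visceral/bone-only disease and practice type, treatment confounded
    by age/stage/ECOG, an exponential progression-free-survival hazard over a
    3-year horizon, and MAR missingness concentrated in ECOG (~29%), stage
    (~7%) and race (~5%).
    """
    covariates = [
        CovariateSpec(
            "age",
            "continuous",
            original={"mean": 66.6, "sd": 11.0},
            target={"mean": 64.9, "sd": 12.6},
        ),
        CovariateSpec(
            "race",
            "categorical",
            original={"probs": [0.77, 0.08, 0.03, 0.12]},
            target={"probs": [0.735, 0.115, 0.026, 0.124]},
            levels=["white", "black", "asian", "other"],
        ),
        CovariateSpec(
            "stage",
            "categorical",
            original={"probs": [0.15, 0.39, 0.23, 0.23]},
            target={"probs": [0.14, 0.30, 0.18, 0.38]},
            levels=["I", "II", "III", "IV"],
        ),
        CovariateSpec(
            # real first-line eligibility excludes ECOG >= 3; a structural zero
            # would quasi-separate the participation model, so the default
            # keeps a sliver of mass at the top level
            "ecog",
            "categorical",
            original={"probs": [0.41, 0.42, 0.13, 0.04]},
            target={"probs": [0.49, 0.36, 0.14, 0.01]},
            levels=["0", "1", "2", "3plus"],
        ),
        CovariateSpec(
            "visceral",
            "binary",
            original={"p": 0.424},
            target={"p": 0.385},
        ),
        CovariateSpec(
            "bone_only",
            "binary",
            original={"p": 0.326},
            target={"p": 0.311},
        ),
        CovariateSpec(
            "community_practice",
            "binary",
            original={"p": 0.915},
            target={"p": 0.994},
        ),
    ]
    treatment_model = {
        "intercept": -1.1,
        "coef": {
            "age": 0.015,
            "stage": {"II": 0.5, "III": 0.4, "IV": -0.6},
            "ecog": {"1": -0.2, "2": -0.3, "3plus": -0.4},
            "visceral": 0.2,
        },
    }
    outcome_model = {
        "baseline": "exponential",
        "lambda0": 1.6e-3,  # per day; median rwPFS ~ 1.2 years at lp = 0
        "shape": 1.0,
        "treatment": 0.10,
        "coef": {
            "age": 0.005,
            "ecog": {"1": 0.25, "2": 0.5, "3plus": 0.8},
            "visceral": 0.3,
            "stage": {"IV": 0.2},
        },
        "interactions": {"visceral": 0.15},
    }
    missing = (
        [
            MissingnessSpec("race", rate=0.055),
            MissingnessSpec("stage", rate=0.075),
            MissingnessSpec("ecog", rate=0.29),
        ]
        if missingness
        else []
    )
    return SimulationConfig(
        n_original=n_original,
        n_target=n_target,
        covariates=covariates,
        treatment_model=treatment_model,
        outcome_model=outcome_model,
        censoring={"horizon": 1095.0, "rate": 5e-4},
        missingness=missing,
        seed=seed,
    )
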