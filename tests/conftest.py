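import numpy as np
import pytest

from iopw.simulate import CovariateSpec, SimulationConfig


def make_config(
    n_original=2000,
    n_target=1000,
    gamma=None,
    beta_treatment=np.log(1.5),
    beta_cov=None,
    interactions=None,
    selection=None,
    horizon=1e9,
    censor_rate=0.0,
    missingness=(),
    seed=0,
    target_shift=0.0,
):
    """Two-covariate config (x1 continuous, x2 binary) for fast simulations."""
    gamma = {} if gamma is None else gamma
    beta_cov = {} if beta_cov is None else beta_cov
    return SimulationConfig(
        n_original=n_original,
        n_target=n_target,
        covariates=[
            CovariateSpec(
                "x1", "continuous", {"mean": 0.0, "sd": 1.0}, {"mean": target_shift, "sd": 1.0}
            ),
            CovariateSpec("x2", "binary", {"p": 0.5}),
        ],
        treatment_model={"intercept": 0.0, "coef": gamma},
        outcome_model={
            "baseline": "exponential",
            "lambda0": 0.002,
            "shape": 1.0,
            "treatment": beta_treatment,
            "coef": beta_cov,
            "interactions": interactions or {},
        },
        selection_model=selection,
        censoring={"horizon": horizon, "rate": censor_rate},
        missingness=list(missingness),
        seed=seed,
    )


@pytest.fixture
def confounded_config():
    """Confounding: x1, x2 drive both treatment and hazard."""
    return make_config(
        gamma={"x1": 0.8, "x2": 0.6},
        beta_cov={"x1": 0.4, "x2": 0.3},
        horizon=1095.0,
        seed=42,
    )
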