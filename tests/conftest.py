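import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from timediet import (
    GeneratorConfig,
    ReferenceProfile,
    TIME_USE_PARTS,
    generate_cohort,
    replace_zeros,
    score_cohort,
)
from timediet.io import complete_case_filter
from timediet.model import fit_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

DURATION_COLUMNS = list(TIME_USE_PARTS)


def make_analytic_sample(config: GeneratorConfig, seed: int):
    """Full preprocessing chain: generate -> score -> filter -> zero-replace."""
    cohort, truth = generate_cohort(config, seed=seed)
    scored = score_cohort(cohort)
    analytic, attrition = complete_case_filter(scored)
    analytic[DURATION_COLUMNS] = replace_zeros(
        analytic[DURATION_COLUMNS].to_numpy(dtype=float), cap=config.zero_cap
    )
    return analytic, truth, attrition


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(n=2000)


@pytest.fixture(scope="session")
def analytic_cohort(default_config):
    """One seeded n=2000 analytic sample with its ground truth."""
    analytic, truth, attrition = make_analytic_sample(default_config, seed=20260929)
    return analytic, truth


@pytest.fixture(scope="session")
def fitted(analytic_cohort):
    """Model fit with the transform fixed at the generator's truth."""
    analytic, truth = analytic_cohort
    model = fit_model(analytic, lam=truth["lam"], shift=truth["shift"])
    return model, truth


@pytest.fixture(scope="session")
def toy_model():
    """Hand-built identity-transform model with one nonzero diet slope.

    lam=1 makes the back-transform affine, so a predicted difference is
    exactly coefficient x delta and every banding decision can be checked
    by hand.
    """
    from timediet.compositional import make_sbp
    from timediet.model import FittedModel

    names = ["const"] + [f"z{i}" for i in range(1, 7)] + [
        "fruit_veg", "discretionary", "ssb", "age", "sex", "sep",
    ]
    params = pd.Series(0.0, index=names)
    params["const"] = 81.0  # bc(y,1)=y-1 -> reference score 82
    params["fruit_veg"] = 1.0
    zeros = pd.Series(0.0, index=names)
    return FittedModel(
        lam=1.0,
        shift=0.0,
        params=params,
        bse=zeros + 1.0,
        pvalues=zeros,
        sigma2=1.0,
        n=100,
        df_resid=87,
        sbp=make_sbp(),
        part_order=TIME_USE_PARTS,
        x_sd=pd.Series(1.0, index=names[1:]),
        t_sd=1.0,
        covariate_fix={"age": 14.4, "sex": 0.0, "sep": 0.0},
    )


@pytest.fixture(scope="session")
def reference():
    return ReferenceProfile(
        time=np.array([740.0, 130, 160, 170, 50, 130, 60]),
        diet=np.array([4.0, 2.0, 1.0]),
    )
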