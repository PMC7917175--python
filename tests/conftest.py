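import numpy as np
import pandas as pd
import pytest

from immunoscape import GeneratorConfig, generate_cohort, preprocess_expression


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast cohort: 5 subtypes, two modules, planted antigens."""
    return GeneratorConfig(
        n_samples=80, n_validation=40, n_genes=120, n_subtypes=3,
        delta=4.0, module_sizes=(30, 30),
        log_hazard_by_subtype=(-0.5, 0.0, 0.5),
        tmb_mean_by_subtype=(20.0, 40.0, 60.0),
        n_normal=20, n_dropout_genes=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_cohort(small_cfg, seed=11)


@pytest.fixture(scope="session")
def small_expr(small_bundle):
    return preprocess_expression(small_bundle.expression)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def exp_surv_data(rng, n, log_hr=0.0, base=0.01, censor=0.005):
    """Exponential survival with a binary covariate; continuous (tie-free)."""
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (base * np.exp(log_hr * x)))
    c = rng.exponential(1.0 / censor, n) if censor > 0 else np.full(n, np.inf)
    return x, np.minimum(t, c), (t <= c).astype(int)
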