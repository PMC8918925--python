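import numpy as np
import pytest

from afhf.cohort import CohortConfig, simulate_cohort
from afhf.pipeline import RunConfig, build_feature_table, load_or_simulate


def random_af_segment(rng, n=375, mean_rr=650.0, cv=0.18, rho=0.3):
    """AF-like random RR segment: log-normal AR(1) tachogram."""
    sigma = np.sqrt(np.log1p(cv**2))
    innov = sigma * np.sqrt(1 - rho**2) * rng.standard_normal(n)
    eps = np.empty(n)
    eps[0] = sigma * rng.standard_normal()
    for i in range(1, n):
        eps[i] = rho * eps[i - 1] + innov[i]
    return mean_rr * np.exp(eps - sigma**2 / 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_cohort_table():
    """Featurized 52-patient cohort with short (90-min) day recordings;
    strong default class effects, shared across model-level tests."""
    cfg = RunConfig(
        cohort=CohortConfig(n_per_class=26, duration_h=1.5), seed=11,
    )
    series, _ = load_or_simulate(cfg)
    return build_feature_table(series, cfg)


@pytest.fixture(scope="session")
def tiny_series():
    cfg = CohortConfig(n_per_class=1, duration_h=2.0, seed=5)
    series, _ = simulate_cohort(cfg)
    return series
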