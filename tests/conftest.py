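import numpy as np
import pytest

from lbpnet import (
    CohortSpec,
    EnetConfig,
    EvalConfig,
    cohort_feature_table,
    generate_cohort,
)

# small grids keep repeated-protocol tests fast; the full study grids are
# exercised separately in the selection unit tests
FAST_ENET = EnetConfig(lambda_grid=(0.5,), alpha_grid=(0.0011,), cv_folds=4)
FAST_EVAL = dict(cost_grid=(1.0,), cv_folds=4, cv_repeats=1)


@pytest.fixture(scope="session")
def effect_cohort():
    """60-node cohort with 8 affected nodes carrying a strong effect."""
    spec = CohortSpec(
        n_hc=25, n_lbp=25, n_nodes=60, n_timepoints=200,
        n_affected=8, effect_size=2.0, seed=3,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def effect_features(effect_cohort):
    X, y = cohort_feature_table(effect_cohort, metrics=("BC", "CC", "DC"))
    return X, y


@pytest.fixture(scope="session")
def null_features():
    spec = CohortSpec(
        n_hc=25, n_lbp=25, n_nodes=60, n_timepoints=200,
        n_affected=0, effect_size=0.0, seed=11,
    )
    cohort = generate_cohort(spec)
    return cohort_feature_table(cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def fast_eval(**kw) -> EvalConfig:
    merged = {**FAST_EVAL, **kw}
    return EvalConfig(**merged)
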