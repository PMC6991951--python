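import numpy as np
import pandas as pd
import pytest

from relifex import (
    BlockSpec,
    InformativeEffect,
    SyntheticSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def two_block_cohort():
    """2000 patients, 20 negatively + 10 positively polarized Likert items."""
    spec = SyntheticSpec(
        n_patients=2000,
        block_specs=[
            BlockSpec(20, "negative", 0.5),
            BlockSpec(10, "positive", 0.5),
        ],
        inter_block_rho=-0.3,
        informative_features=(
            InformativeEffect(0, 1.0),
            InformativeEffect(20, -0.7),
        ),
        noise_sd=0.8,
        seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """400 patients, 8 correlated items + 4 noise columns, 2 planted effects."""
    spec = SyntheticSpec(
        n_patients=400,
        block_specs=[BlockSpec(8, "negative", 0.3)],
        inter_block_rho=0.0,
        n_noise_features=4,
        informative_features=(
            InformativeEffect(0, 1.0),
            InformativeEffect(1, 0.8),
        ),
        noise_sd=0.5,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def xy_small(small_signal_cohort):
    from relifex import encode_features

    X = encode_features(small_signal_cohort).values
    y = (small_signal_cohort.tq_t1 > 46).astype(int)
    return X, y


@pytest.fixture(scope="session")
def fitted_gbt(xy_small):
    from xgboost import XGBClassifier

    X, y = xy_small
    model = XGBClassifier(
        n_estimators=40, max_depth=3, tree_method="hist",
        eval_metric="logloss", random_state=0,
    ).fit(X, y)
    return model, X, y
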