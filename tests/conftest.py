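import numpy as np
import pandas as pd
import pytest

from metscreen.cohort import CASE_LABEL, CONTROL_LABEL, CohortMatrix, FeatureMeta
from metscreen.synth import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_cohort(case_cols, control_cols, kinds=None, panels=None):
    """Assemble a CohortMatrix from per-feature (case, control) sample dicts."""
    names = list(case_cols)
    n1 = len(next(iter(case_cols.values())))
    n2 = len(next(iter(control_cols.values())))
    values = pd.DataFrame(
        {n: np.concatenate([case_cols[n], control_cols[n]]).astype(float) for n in names},
        index=[f"p{i:03d}" for i in range(n1 + n2)],
    )
    groups = pd.Series([CASE_LABEL] * n1 + [CONTROL_LABEL] * n2, index=values.index)
    censored = pd.DataFrame(False, index=values.index, columns=values.columns)
    features = [
        FeatureMeta(
            n,
            (panels or {}).get(n, "metabolon"),
            (kinds or {}).get(n, "continuous"),
        )
        for n in names
    ]
    return CohortMatrix(values=values, censored=censored, groups=groups, features=features)


@pytest.fixture
def make_cohort():
    return build_cohort


@pytest.fixture(scope="session")
def small_synthetic():
    """A small, structured synthetic cohort shared across tests."""
    cfg = GeneratorConfig(
        n_features=60,
        n_clusters=3,
        cluster_size_range=(5, 8),
        censor_quantile=0.05,
        seed=7,
    )
    return generate_cohort(cfg)
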