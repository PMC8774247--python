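import numpy as np
import pandas as pd
import pytest

from radsel.schema import build_default_schema
from radsel.simulate import compact_schema, generate_cohort, generate_feature_table
from radsel.tables import CASE, CONTROL, FeatureTable


@pytest.fixture(scope="session")
def default_schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_schema():
    return compact_schema()


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_table(small_schema, cohort):
    """Compact (288-feature) table with the eight default planted effects."""
    return generate_feature_table(small_schema, cohort["group"], seed=12)


def make_toy_table(n_case=20, n_control=20, n_features=10, d=0.0, seed=0,
                   effect_col=0):
    """Gaussian toy table with an optional standardized effect on one column."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    labels = pd.Series(
        [CASE] * n_case + [CONTROL] * n_control,
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
        name="group",
    )
    X = rng.standard_normal((n, n_features))
    if d:
        X[:n_case, effect_col] += d
    data = pd.DataFrame(X, index=labels.index,
                        columns=[f"f{j}" for j in range(n_features)])
    return FeatureTable(data, labels)
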