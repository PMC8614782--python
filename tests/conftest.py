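import numpy as np
import pandas as pd
import pytest

from soacml.table import DESCRIPTOR, FINGERPRINT_BIT, FeatureTable


def make_table(values, names=None, kind=DESCRIPTOR, ids=None) -> FeatureTable:
    """Build a FeatureTable from a plain array for tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"f{i:02d}" for i in range(p)]
    ids = ids or [f"s{i:03d}" for i in range(n)]
    df = pd.DataFrame(values, index=ids, columns=names)
    return FeatureTable(df, {c: kind for c in names})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng):
    return make_table(rng.normal(size=(30, 6)))


#: tiny hyperparameters so grid tests stay fast
FAST_HP = {
    "xgboost": {"n_estimators": 30},
    "lightgbm": {"n_estimators": 30, "min_child_samples": 2},
    "random_forest": {"n_estimators": 30},
    "adaboost": {"n_estimators": 15},
    "lasso": {},
    "dnn": {"hidden_layer_sizes": (8,), "max_iter": 300},
}
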