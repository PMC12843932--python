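import numpy as np
import pandas as pd
import pytest

from lipodisc import FeatureTable


def build_table(values, missing=None, classes=None, genders=None, batches=None):
    """Construct a small valid FeatureTable around a value matrix.

    Rows are grouped in consecutive triplets per individual when the row
    count is divisible by 3, otherwise one individual per row.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    reps = 3 if n % 3 == 0 else 1
    n_ind = n // reps
    if classes is None:
        classes = ["BD" if i < (n_ind + 1) // 2 else "SCH" for i in range(n_ind)]
    if genders is None:
        genders = ["M" if i % 2 == 0 else "F" for i in range(n_ind)]
    if batches is None:
        batches = [1 + (i * 2) // n for i in range(n)]
    ind_of_row = np.repeat(np.arange(n_ind), reps)
    obs_meta = pd.DataFrame(
        {
            "obs_id": [f"O{i:03d}" for i in range(n)],
            "individual_id": [f"P{ind_of_row[i]:03d}" for i in range(n)],
            "replicate": np.tile(np.arange(1, reps + 1), n_ind),
            "class_label": [classes[ind_of_row[i]] for i in range(n)],
            "gender": [genders[ind_of_row[i]] for i in range(n)],
            "batch": batches,
        }
    )
    feat_meta = pd.DataFrame(
        {
            "feature_id": range(p),
            "name": [f"F{j:02d}" for j in range(p)],
            "mz": 300.0 + np.arange(p),
            "rt": 1.0 + 0.1 * np.arange(p),
            "metabolite_id": [f"M{j:02d}" for j in range(p)],
        }
    )
    if missing is None:
        missing = np.isnan(values)
    vals = values.copy()
    vals[missing] = np.nan
    return FeatureTable(vals, np.asarray(missing, dtype=bool), obs_meta, feat_meta)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    return build_table(10.0 ** rng.uniform(3, 5, size=(6, 4)))
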