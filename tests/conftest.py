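import numpy as np
import pandas as pd
import pytest

from depselect.io import IntensityMatrix, SampleTable


def make_matrix(values, samples=None, ids=None, mask=None, genes=None):
    """Build an IntensityMatrix from a nested list (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    ids = ids or [f"P{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    values_df = pd.DataFrame(
        arr, index=pd.Index(ids, name="protein_id"), columns=samples
    )
    mask_df = values_df.isna() if mask is None else pd.DataFrame(
        mask, index=ids, columns=samples
    )
    genes_s = None if genes is None else pd.Series(genes, index=ids)
    return IntensityMatrix(values_df.mask(mask_df), mask_df, genes_s)


def make_samples(n_per_group=5, groups=("A", "B"), batches=None):
    rows = []
    i = 0
    for g in groups:
        for k in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{g}{k + 1}",
                    "group": g,
                    "batch": str(batches[i] if batches else 1),
                }
            )
            i += 1
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def toy_matrix():
    return make_matrix(
        [
            [2.0, None, 3.0, 2.5],
            [5.0, 5.5, 6.0, 5.2],
            [None, None, 1.0, 1.2],
        ],
        samples=["A1", "A2", "B1", "B2"],
    )


@pytest.fixture
def two_group_labels():
    return pd.Series(
        ["A", "A", "B", "B"], index=["A1", "A2", "B1", "B2"], name="group"
    )


@pytest.fixture
def separable_xy():
    """10 samples, one perfectly separating feature and one noise feature."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        {
            "sep": np.r_[rng.normal(0, 0.3, 5), rng.normal(4, 0.3, 5)],
            "noise": rng.normal(0, 1, 10),
        }
    )
    y = np.array(["A"] * 5 + ["B"] * 5)
    return X, y
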