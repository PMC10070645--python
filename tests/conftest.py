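import numpy as np
import pandas as pd
import pytest

from snfcc import CohortSpec, FeatureBlock, generate_cohort, preprocess_blocks


def numeric_block(values, name="b", role="numeric_only"):
    """Build a numeric FeatureBlock; a 1-d input is one variable."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    df = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(values.shape[0])],
        columns=[f"v{j}" for j in range(values.shape[1])],
    )
    return FeatureBlock(name, df, {c: "numeric" for c in df.columns}, role)


def block_diagonal_similarity(sizes, within=1.0, between=0.0):
    """Exact block-diagonal similarity matrix with unit diagonal."""
    n = sum(sizes)
    A = np.full((n, n), between)
    start = 0
    for s in sizes:
        A[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(A, 1.0)
    return A


@pytest.fixture(scope="session")
def cohort3():
    """Planted 3-cluster cohort, strong separation."""
    return generate_cohort(
        CohortSpec(
            n_subjects=60,
            cluster_proportions=(1 / 3, 1 / 3, 1 / 3),
            effect_size=2.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def preprocessed3(cohort3):
    blocks, _ = preprocess_blocks([b.copy() for b in cohort3.blocks])
    return blocks
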