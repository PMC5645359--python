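"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from sticomics import (
    CohortConfig,
    ExpressionMatrix,
    NormalPoolConfig,
    generate_normal_pools,
    generate_tumor_expression,
)
from sticomics.preprocess import log_normalize, size_factors

SMALL_COHORT = CohortConfig(
    n_stic=20, n_nostic=20, n_genes=2000, subtype_sep=3.0, seed=11
)
SMALL_NORMALS = NormalPoolConfig(
    n_genes=2000, n_ft_markers=400, n_ov_markers=60, n_per_markers=60, seed=11
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_tumor_expression(SMALL_COHORT)


@pytest.fixture(scope="session")
def small_cohort_log(small_cohort):
    m = small_cohort.matrix
    return log_normalize(m, size_factors(m))


@pytest.fixture(scope="session")
def small_normals():
    return generate_normal_pools(SMALL_NORMALS)


@pytest.fixture(scope="session")
def small_normals_log(small_normals):
    m = small_normals.matrix
    return log_normalize(m, size_factors(m))


@pytest.fixture()
def toy_counts():
    """4 genes x 3 samples of raw counts with annotations."""
    vals = pd.DataFrame(
        [[10, 20, 30], [5, 10, 15], [100, 200, 300], [1, 2, 3]],
        index=["gA", "gB", "gC", "gD"],
        columns=["s1", "s2", "s3"],
    )
    ann = pd.DataFrame({"group": ["STIC", "STIC", "NOSTIC"]}, index=vals.columns)
    return ExpressionMatrix(vals, state="raw_counts", annotations=ann)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)
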