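import numpy as np
import pandas as pd
import pytest

from pairsig.io import ExpressionMatrix
from pairsig.synthetic import CohortSpec, generate_cohort


def make_expr(values, gene_ids=None, sample_ids=None, classes=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a raw array for quick fixtures."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_g, n_s = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_g)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_s)]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    if classes is None:
        cls = pd.Series("other", index=df.index)
    else:
        cls = pd.Series(list(classes), index=df.index)
    return ExpressionMatrix(df, cls)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(
        n_tumor=150,
        n_normal=30,
        n_lnc=24,
        n_mrna=60,
        n_immune_mrna=20,
        n_corr_lnc=16,
        n_de_lnc=10,
        planted_pairs=[(0, 1, 1.0), (2, 3, -1.0)],
        censor_rate=0.25,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """(expression, clinical, truth) for a modest planted-signal cohort."""
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def tumor_ids(small_cohort):
    _, clinical, _ = small_cohort
    return list(clinical["sample_id"])
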