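import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoclass.simulate import CohortConfig, generate_cohort
from phenoclass.types import ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-settings synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    return generate_cohort(CohortConfig(seed=11).noise_free())
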