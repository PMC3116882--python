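import numpy as np
import pandas as pd
import pytest

from awasig import CohortSpec, ExpressionMatrix, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples with easily hand-checked values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 8.0]],
        index=["pA", "pB", "pC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-size synthetic cohort shared by unit tests (fast)."""
    spec = CohortSpec(n_probes=400, seed=7)
    return generate_cohort(spec)


def random_matrix(n_probes: int, n_samples: int, seed: int = 0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(8, 1, (n_probes, n_samples)),
        index=[f"p{i:04d}" for i in range(n_probes)],
        columns=[f"s{i:03d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(values)
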