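import numpy as np
import pandas as pd
import pytest

from reosig import ClinicalTable, ExpressionMatrix, GeneratorConfig, generate_cohort


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """4 genes x 3 samples with hand-set orderings."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [5.0, 3.0, 1.0, 2.0],
                "s2": [2.0, 4.0, 6.0, 1.0],
                "s3": [3.0, 3.0, 2.0, 7.0],
            },
            index=["gA", "gB", "gC", "gD"],
        )
    )


@pytest.fixture
def small_clinical() -> ClinicalTable:
    return ClinicalTable(
        pd.DataFrame(
            {
                "rfs_months": [12.0, 30.0, 72.0],
                "event": [1, 0, 1],
                "response_state": ["CR", "nonCR", None],
                "age_years": [55.0, 63.0, np.nan],
                "stage": ["III", "IV", "II"],
                "grade": [3, 2, 3],
                "residual": ["0-10mm", ">=11mm", None],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One reference synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=7))


def random_survival(rng, n, censor_frac=0.3):
    """Small random censored survival instance for oracle comparisons."""
    times = rng.exponential(10.0, size=n).round(3)
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[int(rng.integers(n))] = 1
    return times, events
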