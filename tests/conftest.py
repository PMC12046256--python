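import numpy as np
import pandas as pd
import pytest

from synthcohort import (
    ColumnSpec,
    CohortSchema,
    CohortTable,
    FixtureConfig,
    RHVAEConfig,
    TabularProcessor,
    generate_fixture,
)
from synthcohort.rhvae import train


@pytest.fixture(scope="session")
def tiny_schema() -> CohortSchema:
    return CohortSchema(
        (
            ColumnSpec("age", "numerical", min=0, max=100, integer_valued=True),
            ColumnSpec("score", "numerical", min=0.0, max=1.0),
            ColumnSpec("sex", "binary", levels=("F", "M")),
            ColumnSpec("grade", "categorical", levels=("A", "B", "C")),
        )
    )


@pytest.fixture
def tiny_table(tiny_schema) -> CohortTable:
    df = pd.DataFrame(
        {
            "age": [20.0, 50.0, 80.0, 35.0],
            "score": [0.1, 0.9, 0.5, 0.25],
            "sex": ["F", "M", "F", "F"],
            "grade": ["A", "B", "C", "A"],
        }
    )
    return CohortTable(schema=tiny_schema, data=df)


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    return generate_fixture(FixtureConfig(n_patients=150, seed=3))


@pytest.fixture(scope="session")
def small_trained(small_cohort):
    """A briefly but genuinely trained model on a 150-patient cohort."""
    encoded = TabularProcessor(small_cohort.schema).fit_transform(small_cohort)
    config = RHVAEConfig(epochs=120, batch_size=32, seed=7)
    return train(encoded, config)


@pytest.fixture(scope="session")
def barely_trained(small_cohort):
    """Same architecture after a single epoch: the ablation baseline."""
    encoded = TabularProcessor(small_cohort.schema).fit_transform(small_cohort)
    config = RHVAEConfig(epochs=1, batch_size=32, seed=7)
    return train(encoded, config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
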