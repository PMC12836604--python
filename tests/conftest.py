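import numpy as np
import pytest

from hnsurv import (
    GeneratorConfig,
    builtin_published_model,
    cohort_records,
    generate_cohort,
)


@pytest.fixture(scope="session")
def published_model():
    return builtin_published_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A 275-subject synthetic cohort under the default study conditions."""
    df, _ = generate_cohort(GeneratorConfig(n=275, seed=101))
    return cohort_records(df)


@pytest.fixture(scope="session")
def small_cohort_frame():
    df, _ = generate_cohort(GeneratorConfig(n=275, seed=101))
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
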