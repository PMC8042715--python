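import numpy as np
import pytest

import batchfocus as bf


@pytest.fixture(scope="session")
def small_cohort() -> bf.Cohort:
    """A small but batch-divisible synthetic cohort for fast trainer tests."""
    return bf.generate(
        bf.GeneratorConfig(n=130, minority_rate=0.15, effect_size=1.5, seed=5)
    )


@pytest.fixture(scope="session")
def reference_pools() -> bf.ReferenceCohorts:
    return bf.reference_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
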