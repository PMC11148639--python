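import numpy as np
import pandas as pd
import pytest

from immunomodules import CohortSpec, generate_feature_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort: 8 modules x 6 features, rho 0.8."""
    spec = CohortSpec(seed=1, discriminative_modules={0: 1.5})
    return generate_feature_cohort(spec)


@pytest.fixture
def toy_table():
    """Tiny deterministic feature table: two correlated pairs + one noise."""
    rng = np.random.default_rng(7)
    n = 12
    f1 = rng.standard_normal(n)
    f2 = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    values = pd.DataFrame(
        {
            "a1": f1,
            "a2": f1 + 0.01 * rng.standard_normal(n),
            "b1": f2,
            "b2": f2 + 0.01 * rng.standard_normal(n),
            "noise": noise,
        },
        index=[f"S{i}" for i in range(n)],
    )
    return values
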