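import numpy as np
import pytest

import multilink as ml


@pytest.fixture
def tiny_cohort():
    """Smallest useful symmetric cohort: 4 subjects, 4 nodes, 2 per group."""
    rng = np.random.default_rng(7)
    mats = []
    for _ in range(4):
        a = rng.standard_normal((4, 4))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 0.0)
        mats.append(m)
    return ml.ConnectomeCohort(
        subjects=[f"s{i}" for i in range(4)],
        matrices=np.stack(mats),
        labels=np.array([0, 0, 1, 1]),
        symmetric=True,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Reference recovery cohort: 15+15 subjects, 32 nodes, 5 edges at d=2."""
    cohort, truth = ml.generate_cohort(ml.planted_effect_spec(seed=0))
    return cohort, truth


@pytest.fixture(scope="session")
def planted_design(planted_cohort):
    cohort, truth = planted_cohort
    return ml.vectorize(cohort), truth
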