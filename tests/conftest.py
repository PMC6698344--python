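import warnings

import numpy as np
import pytest

from tbmscreen import EffectModel, default_atlas, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def default_dataset():
    """One simulator-default dataset shared by read-only tests."""
    return simulate_cohort(EffectModel(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset for pipeline plumbing tests."""
    em = EffectModel(
        seed=7,
        n_per_group={"Ctrl": 8, "PreAD": 6, "MCI_AD": 4},
        visits_per_subject={2: 1.0},
    )
    return simulate_cohort(em)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
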