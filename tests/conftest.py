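import numpy as np
import pytest

from rrverify.preprocess import preprocess_series
from rrverify.synthetic_data import (
    CohortSpec,
    high_separability_distributions,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight well-separated subjects, one basal minute each at 6 months."""
    spec = CohortSpec(
        n_subjects=8,
        ages_months=(6.0,),
        conditions=("basal",),
        segment_duration=60.0,
        seed=42,
    )
    return simulate_cohort(spec, high_separability_distributions())


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    """50-beat windows from the small cohort (several per subject)."""
    windows = []
    for s in small_cohort:
        windows.extend(preprocess_series(s, 50))
    return windows
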