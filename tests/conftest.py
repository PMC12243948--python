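import numpy as np
import pytest

from emodyn.synth import SimSpec, simulate_cohort
from emodyn.timeline import all_builtin_timelines


@pytest.fixture(scope="session")
def timelines():
    return all_builtin_timelines()


@pytest.fixture(scope="session")
def tlA1(timelines):
    return timelines[("A", 1)]


@pytest.fixture(scope="session")
def small_cohort(timelines):
    """A cohort at desk scale with ideal anatomical alignment, shared by
    the analysis tests (context shift and timing delay both on)."""
    spec = SimSpec(
        n_subjects=8, n_units=40, n_features=20, snr=1.0,
        context_shift=0.5, timing_delay_tr=4, shared_voxel_map=True, seed=7,
    )
    return simulate_cohort(spec, timelines)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
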