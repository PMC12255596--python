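import numpy as np
import pytest

import qsmref as q


@pytest.fixture(scope="session")
def phantom():
    """Default 48^3 piecewise-constant phantom with the nine standard ROIs."""
    return q.build_phantom((48, 48, 48))


@pytest.fixture(scope="session")
def suite(phantom):
    """Smoothed ground truth plus six reconstruction emulators."""
    gt, _ = phantom
    return q.reconstruction_suite(gt, smooth_sigma=1.0, seed=0)


@pytest.fixture(scope="session")
def cohort_table():
    """A null-design cohort table (27/19/17 subjects, no group effects)."""
    design = q.default_cohort_design(seed=7)
    return q.cohort_to_frame(q.simulate_cohort(design))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
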