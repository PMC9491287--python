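import numpy as np
import pytest

from qcfcbench import BoldSeries, RealignmentParams
from qcfcbench.synthetic import CohortSpec, simulate_cohort, simulate_motion_trace


@pytest.fixture(scope="session")
def pinned_motion() -> RealignmentParams:
    """A 300-volume simulated trace (severity 1, 2 spikes/100 volumes) whose
    Jenkinson FD exceeds the 0.25 mm spike threshold at least once."""
    return simulate_motion_trace(300, severity=1.0, spike_rate=2.0, seed=7)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Desk-scale cohort spec for fast end-to-end tests."""
    return CohortSpec(
        n_subjects=12, n_rois=20, n_volumes=160, n_voxels_per_tissue=64,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def roi_series(data: np.ndarray, tr: float = 2.0) -> BoldSeries:
    return BoldSeries(data=np.asarray(data, dtype=float), tr=tr, space="roi")
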