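import numpy as np
import pytest

from fcmech.containers import Volume4D
from fcmech.synthetic import CohortConfig, make_rsn_templates, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_templates():
    return make_rsn_templates((14, 14, 10), 3, seed=7)


def make_volume(data, tr=2.5, voxel_mm=(3.75, 3.75, 4.0), mask=None):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return Volume4D(data=np.asarray(data, float), affine=aff, tr=tr, mask=mask)


@pytest.fixture
def tiny_cohort():
    """Small noiseless-free cohort shared by integration-flavoured tests."""
    cfg = CohortConfig(
        n_hc=6, n_ms_short=5, n_ms_long=4, grid=(14, 14, 10), T=60, n_networks=3,
        scenario_effects=[],
    )
    vols, design, truth = simulate_cohort(cfg, seed=42)
    return cfg, vols, design, truth
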