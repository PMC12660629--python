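import numpy as np
import pytest

import nirsconn as nc


@pytest.fixture(scope="session")
def montage():
    return nc.build_montage()


@pytest.fixture(scope="session")
def small_cohort():
    """Small full-chain cohort (optics + noise + artifacts), reused read-only."""
    spec = nc.CohortSpec(
        n_mt=4, n_wl=3, n_hc=3, duration_s=120.0, master_seed=11
    )
    return nc.simulate_cohort(spec)


@pytest.fixture(scope="session")
def fast_cohort():
    """Fast-path cohort (clean concentration series), reused read-only."""
    spec = nc.CohortSpec(
        n_mt=8, n_wl=4, n_hc=4, duration_s=120.0, master_seed=13, optics=False
    )
    return nc.simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def clean_recording(montage):
    """Noise- and artifact-free recording with known hemodynamics."""
    spec = nc.CohortSpec(
        n_mt=2, n_wl=2, n_hc=2, duration_s=120.0, master_seed=5,
        noise=nc.NULL_NOISE,
    )
    bundle = nc.simulate_cohort(spec)
    return bundle, bundle.recordings[("MT01", "T1")]
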