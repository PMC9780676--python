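import warnings

import numpy as np
import pytest

import fnirslat as fl

warnings.filterwarnings("ignore", category=RuntimeWarning, module="fnirslat")


@pytest.fixture(scope="session")
def montage():
    return fl.build_montage()


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Tiny cohort with all nuisance processes off: recordings carry only
    the lateralized evoked response, so the linear chain must invert it."""
    cfg = fl.SimConfig(
        n_participants=2,
        seed=5,
        band_amplitudes={"cardiac": 0.0, "respiration": 0.0, "mayer": 0.0},
        motion_rate=0.0,
        od_noise_sd=0.0,
        trial_noise_sd=0.0,
        short_hrf_fraction=0.0,
    )
    return fl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = fl.SimConfig(n_participants=3, seed=11)
    return fl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def sem_cohort():
    """SEM-scale cohort (trial-level laterality, no optics)."""
    cfg = fl.SimConfig(n_participants=20, n_trials=12, seed=42, true_rho_m1lat=0.6)
    return fl.generate_sem_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
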