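import numpy as np
import pytest

import lgmsens as L

WAVE_TIMES = (0.0, 1.17, 2.17)


@pytest.fixture(scope="session")
def preset():
    params, scenario, n, times = L.study_emulation_preset()
    return params, scenario, n, times


@pytest.fixture(scope="session")
def preset_dataset(preset):
    """One masked draw from the study-emulation preset, with latent record."""
    params, scenario, n, times = preset
    ds, latent = L.simulate_growth(n, times, params, seed=11)
    masked, log = L.impose_missingness(ds, scenario, latent=latent, seed=12)
    return masked, latent, log


@pytest.fixture(scope="session")
def spec():
    return L.GrowthSpec(wave_times=WAVE_TIMES, cov_IS_free=False)


@pytest.fixture(scope="session")
def small_complete():
    """Small complete three-wave dataset with nontrivial correlation."""
    params = L.GrowthParams(mu_I=3.0, mu_S=-0.1, psi_II=0.4, psi_SS=0.03,
                            psi_IS=0.02, theta=0.25)
    ds, _ = L.simulate_growth(300, np.array(WAVE_TIMES), params, seed=5)
    return ds
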