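import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def series20():
    """Small noiseless congeneric series with planted field-space truth."""
    from fieldqsar import synthdata
    return synthdata.make_congeneric_series(20, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def series40():
    """40-compound noiseless series used for recovery checks."""
    from fieldqsar import synthdata
    return synthdata.make_congeneric_series(40, noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def toy_xy():
    """Fixed observed/predicted activity vectors for metric oracles."""
    y_obs = np.array([5.10, 6.25, 7.30, 8.45, 6.60, 7.75])
    y_pred = np.array([5.35, 6.05, 7.60, 8.20, 6.90, 7.50])
    return y_obs, y_pred
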