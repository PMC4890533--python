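import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cryptvillus.qpcr import CpMatrix
from cryptvillus.synthetic_data import SimConfig, generate_bundle

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_cp_matrix() -> CpMatrix:
    """3 assays x 2 samples with one undetected reaction."""
    cp = pd.DataFrame(
        {"s1": [20.0, 25.0, 30.0], "s2": [22.0, np.nan, 28.0]},
        index=["A", "B", "C"],
    )
    groups = pd.Series({"s1": "WTV", "s2": "WTC"})
    return CpMatrix(cp=cp, negative_control=pd.Series(np.nan, index=cp.index),
                    groups=groups)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SimConfig(seed=11))


@pytest.fixture(scope="session")
def quiet_bundle():
    """Near-noise-free bundle: measured directions reflect the planted truth."""
    return generate_bundle(
        SimConfig(seed=11, cp_noise_sd=1e-9, spot_log2_noise_sd=1e-9,
                  marker_noise_sd=0.0)
    )
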