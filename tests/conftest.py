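import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

warnings.filterwarnings("ignore", message=".*ArviZ.*")

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50)
    settings.load_profile("suite")
except ImportError:
    pass


@pytest.fixture
def wt_profile():
    from dogait.synth import GaitProfile

    return GaitProfile(
        phenotype="WT",
        gait_pattern="gallop",
        stride_frequency=2.8,
        axis_amplitudes=(2.0, 0.8, 1.2),
        gyro_amplitudes=(150.0, 300.0, 120.0),
        noise_sd=0.05,
    )


@pytest.fixture
def dys_profile():
    from dogait.synth import GaitProfile

    return GaitProfile(
        phenotype="DYS",
        gait_pattern="trot",
        stride_frequency=2.2,
        axis_amplitudes=(0.8, 0.35, 0.5),
        gyro_amplitudes=(60.0, 120.0, 50.0),
        noise_sd=0.05,
    )


@pytest.fixture
def small_panel():
    """6 dogs x 11 months drawn from a known rising log-scale trend."""
    from dogait.synth import TruePanelParams, generate_panel

    m = tuple(np.log(np.linspace(1.2, 2.0, 11)))
    params = TruePanelParams(
        m=m, sigma0_sq=0.04, sigma1_sq=0.01, beta=0.0, transform="log"
    )
    return generate_panel(
        params, [f"d{i}" for i in range(6)], range(2, 13), seed=5
    )


@pytest.fixture
def fast_mcmc():
    from dogait.trend import MCMCSettings

    return MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=11)
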