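import numpy as np
import pytest

from aaokin.steady_state import SteadyStateParams
from aaokin.synthetic_data import (
    ITC_PRESETS,
    REDUCTION_PRESETS,
    STEADY_STATE_PRESETS,
    NoiseSpec,
    default_itc_design,
)


@pytest.fixture
def peaao_o2_params() -> SteadyStateParams:
    """Steady-state constants for PeAAO / 4-methoxybenzyl alcohol / O2."""
    return STEADY_STATE_PRESETS[("PeAAO", "4-methoxybenzyl", "O2")]


@pytest.fixture
def baaao_reduction_params():
    """Transient reduction constants for BaAAO / 4-methoxybenzyl alcohol."""
    return REDUCTION_PRESETS[("BaAAO", "4-methoxybenzyl")]


@pytest.fixture
def baaao_itc():
    """BaAAO:BQ one-site parameters and the 19 x 2 µL titration design."""
    return ITC_PRESETS["BaAAO"], default_itc_design("BaAAO")


@pytest.fixture
def no_noise() -> NoiseSpec:
    return NoiseSpec(sd=0.0)


@pytest.fixture
def kobs_grid(baaao_reduction_params):
    p = baaao_reduction_params
    return np.linspace(0.25 * p.Kd_alcohol_uM, 6.0 * p.Kd_alcohol_uM, 8)
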