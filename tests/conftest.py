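import numpy as np
import pytest

from chemoplan import ModelParameters, TumorState


@pytest.fixture
def params():
    """A representative treated-tumor parameter set (the calibrated median)."""
    from chemoplan.cohort import DEFAULT_MEDIANS

    return DEFAULT_MEDIANS


@pytest.fixture
def simple_params():
    """Hand-round numbers convenient for closed-form checks."""
    return ModelParameters(
        growth_rate=0.25,
        necrosis_rate=0.05,
        washout_rate=0.15,
        max_kill_rate=0.3,
        ed50=5.0,
        clearance=0.2,
        elimination_vmax=0.1,
        elimination_km=1.0,
    )


@pytest.fixture
def state200():
    return TumorState(200.0, 0.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
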