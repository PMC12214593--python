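import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from bretpharm import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_design():
    """A compact BRET plate design covering baseline and the 2-4 min window."""
    return synthetic.PlateDesign(
        receptors=("b2AR",),
        sensors=("F5",),
        concentrations_uM=(0.001, 0.01, 0.1, 1.0, 10.0),
        timepoints_min=(-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    )


@pytest.fixture
def responder_truth():
    return synthetic.SensorTruth(
        receptor="b2AR",
        sensor="F5",
        bottom=0.0,
        top=0.2,
        log_ec50=-1.0,
        hill=1.0,
        responder=True,
    )
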