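import pytest
from hypothesis import settings

from nicdclock import CellCycleParams, NicdParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cc():
    """Default 16 h cell-cycle calibration."""
    return CellCycleParams()


@pytest.fixture(scope="session")
def kin():
    """Default NICD kinetic rates."""
    return NicdParams()
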