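import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from wbpatlak import (InputFunction, KineticParams, build_schedule,
                      feng4_default, frame_average, split_tac, merge_tacs)


@pytest.fixture(scope="session")
def feng():
    return feng4_default()


@pytest.fixture(scope="session")
def triexp_input():
    """A tri-exponential bolus input (matched to the default gap family)."""
    return InputFunction(
        "tri_exponential",
        {"amplitudes": [60.0, 25.0, 18.0], "rates": [-3.0, -0.12, -0.010]},
        t_peak_offset=0.5)


@pytest.fixture(scope="session")
def standard_schedule():
    return build_schedule("standard")


@pytest.fixture(scope="session")
def two_short_schedule():
    return build_schedule("two_short")


@pytest.fixture(scope="session")
def brainlike_params():
    return KineticParams(K1=0.1, k2=0.15, k3=0.05, vb=0.05)


@pytest.fixture(scope="session")
def merged_idif_triexp(triexp_input, two_short_schedule):
    """Noiseless merged IDIF from the two-short protocol, tri-exp truth."""
    tac = frame_average(triexp_input, two_short_schedule, source="aorta_idif")
    early, late = split_tac(tac, at=6.0)
    return merge_tacs(early, late)
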