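import numpy as np
import pytest

from nmrprofile import simulate as sim
from nmrprofile.model import (
    Cluster,
    CompoundSignature,
    Peak,
    ProfileAssignment,
    SpectralLibrary,
)


@pytest.fixture
def axis():
    """A modest acquisition grid: 12 ppm sweep, 8192 points."""
    return sim.default_axis(8192)


@pytest.fixture
def fine_axis():
    return sim.default_axis(16384)


@pytest.fixture
def single_peak_library():
    sig = CompoundSignature(
        "A", (Cluster("A:0", (Peak(height=2.0, center=3.0, fwhm=0.003),)),)
    )
    return SpectralLibrary([sig])


@pytest.fixture
def two_compound_library():
    a = CompoundSignature(
        "A",
        (
            Cluster("A:0", (Peak(1.0, 2.0, 0.003), Peak(0.5, 2.01, 0.003))),
            Cluster("A:1", (Peak(2.0, 7.0, 0.004),)),
        ),
    )
    b = CompoundSignature("B", (Cluster("B:0", (Peak(1.5, 5.5, 0.003),)),))
    return SpectralLibrary([a, b])


@pytest.fixture
def small_mixture(two_compound_library, axis):
    truth = ProfileAssignment(
        {"A": 100.0, "B": 50.0},
        {"A:0": 0.01, "A:1": -0.005, "B:0": 0.0},
    )
    return two_compound_library, truth, axis
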