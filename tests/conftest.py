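import numpy as np
import pytest

from qclspec.design import a_optimal_design
from qclspec.instrument import InstrumentConfig
from qclspec.optics import PrismGeometry
from qclspec.pipeline import StudyConfig, run_study


@pytest.fixture(scope="session")
def zns_prism() -> PrismGeometry:
    """The ZnS trapezoid: 24 mm top facet, 2.4 mm height, 45 deg facets."""
    return PrismGeometry()


@pytest.fixture(scope="session")
def default_instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def default_design():
    """The 25-sample A-optimal design at the study concentration ranges."""
    return a_optimal_design(seed=0)


@pytest.fixture(scope="session")
def full_study():
    """The complete default study: 25 samples x 4 series x 2 setups, 10 scans.

    Shared session-wide because simulating 400 measurements of 10 scans of
    100,000 pulses is the single most expensive fixture in the suite.
    """
    manifest, results = run_study(StudyConfig(), seed=7)
    return manifest, results
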