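import numpy as np
import pytest

from docseer.catchment import demo_catchment
from docseer.hindcast import reference_run
from docseer.synthetic import ClimateConfig, generate_truth_weather


@pytest.fixture(scope="session")
def climate():
    return ClimateConfig()


@pytest.fixture(scope="session")
def truth10(climate):
    """10-year truth weather record (1988–1997) for both sub-catchments."""
    return generate_truth_weather(climate, 10, seed=42, start_year=1988)


@pytest.fixture(scope="session")
def catchment():
    return demo_catchment()


@pytest.fixture(scope="session")
def reference10(catchment, truth10):
    """Truth-forced reference run with state trajectory over the 10-year record."""
    return reference_run(catchment, truth10)
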