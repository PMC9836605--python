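import pytest

from gabreta import bundled
from gabreta.spatial_filter import load_study_area
from gabreta.synthetic_fixtures import FixtureConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """A mid-sized synthetic world shared by read-only tests."""
    return generate_world(FixtureConfig(seed=42))


@pytest.fixture(scope="session")
def example_converter():
    return bundled.load_example_converter()


@pytest.fixture(scope="session")
def example_registry():
    return bundled.load_example_registry()


RECT_INNER = {
    "type": "Polygon",
    "coordinates": [[[13.262, 48.852], [13.738, 48.852], [13.738, 49.148],
                     [13.262, 49.148], [13.262, 48.852]]],
}
RECT_OUTER = {
    "type": "Polygon",
    "coordinates": [[[13.122, 48.762], [13.878, 48.762], [13.878, 49.238],
                     [13.122, 49.238], [13.122, 48.762]]],
}


@pytest.fixture(scope="session")
def study_area():
    return load_study_area(RECT_INNER, RECT_OUTER)
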