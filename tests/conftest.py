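import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50, database=None)
settings.load_profile("deterministic")

from hrhplan import (
    ProjectionAssumptions,
    StaffingNorms,
    load_packaged_regions,
)


@pytest.fixture(scope="session")
def zimbabwe_panel():
    """Reconciled 2010 Zimbabwe panel: (regions, national total, areas)."""
    return load_packaged_regions()


@pytest.fixture(scope="session")
def regions(zimbabwe_panel):
    return zimbabwe_panel[0]


@pytest.fixture(scope="session")
def national(zimbabwe_panel):
    return zimbabwe_panel[1]


@pytest.fixture(scope="session")
def areas(zimbabwe_panel):
    return zimbabwe_panel[2]


@pytest.fixture()
def assumptions():
    return ProjectionAssumptions()


@pytest.fixture()
def norms():
    return StaffingNorms()


def region_named(regions, name):
    return next(r for r in regions if r.name == name)
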