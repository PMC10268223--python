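import pytest
from hypothesis import settings

import icukit
from icukit.load import load_concepts
from icukit.sources import register_source
from icukit.synth import DIALECTS, FIXTURE_N, FIXTURE_SEED, render_source

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_truth():
    """The canonical test cohort."""
    return icukit.generate_cohort(FIXTURE_SEED, FIXTURE_N)


@pytest.fixture(scope="session")
def dictionary():
    return icukit.load_dictionary()


@pytest.fixture(scope="session")
def rendered(fixture_truth, tmp_path_factory):
    """The canonical cohort rendered into all three dialects, registered."""
    root = tmp_path_factory.mktemp("cohort")
    handles = {}
    for dia in DIALECTS:
        cfg = render_source(fixture_truth, dia, root / dia)
        handles[dia] = register_source(cfg, root / dia)
    return handles


@pytest.fixture(scope="session")
def abs_handle(rendered):
    return rendered["eav_absolute"]


@pytest.fixture(scope="session")
def small_truth():
    return icukit.generate_cohort(11, 30)


@pytest.fixture(scope="session")
def small_handle(small_truth, tmp_path_factory):
    root = tmp_path_factory.mktemp("small")
    cfg = render_source(small_truth, "eav_absolute", root)
    return register_source(cfg, root)
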