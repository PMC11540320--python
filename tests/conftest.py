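import pytest

from allorelic import default_fixture
from allorelic.pipeline import run_full


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    """The published default fixture (seed 42), generated once per session."""
    return default_fixture(str(tmp_path_factory.mktemp("fixture")))


@pytest.fixture(scope="session")
def pipeline_results(fixture, tmp_path_factory):
    outdir = str(tmp_path_factory.mktemp("pipeline"))
    return run_full(fixture, outdir, seed=1), outdir
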