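import json
from pathlib import Path

import pytest

from metabogo import (
    FixtureSpec,
    build_knowledgebase,
    generate_mock_sources,
    worked_example_kb,
)

DATA_DIR = Path(__file__).parent / "data" / "mock_sources"


@pytest.fixture(scope="session")
def mock_bundle(tmp_path_factory):
    """Freshly generated mock sources (default spec, seed 7)."""
    out = tmp_path_factory.mktemp("mock_sources")
    return generate_mock_sources(FixtureSpec(), out)


@pytest.fixture(scope="session")
def truth(mock_bundle):
    return json.loads((mock_bundle.obo_path.parent / "truth.json").read_text())


@pytest.fixture(scope="session")
def kb(mock_bundle):
    return build_knowledgebase(mock_bundle)


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_kb()


@pytest.fixture(scope="session")
def committed_dir():
    """Mock sources committed to the repository, pinned against
    generator drift."""
    return DATA_DIR
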