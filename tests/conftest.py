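import pytest

from nmmkit.cgs import build_cptg
from nmmkit.knowledgebase import generate_fixture_kb, load_kb

FIXTURE_SEED = 1
FIXTURE_N = 12


@pytest.fixture(scope="session")
def kb_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("kb") / "fixture"
    generate_fixture_kb(FIXTURE_SEED, FIXTURE_N, path)
    return path


@pytest.fixture(scope="session")
def kb(kb_dir):
    return load_kb(kb_dir)


@pytest.fixture(scope="session")
def cptg(kb):
    return build_cptg(kb.relations)
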