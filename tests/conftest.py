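import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from methylannot import fixtures as fx


@pytest.fixture(scope="session")
def default_fixture():
    return fx.build_fixture(fx.default_fixture_spec(seed=0))


@pytest.fixture(scope="session")
def demo_gene():
    models, positions = fx.demo_gene_models()
    return models, positions


@pytest.fixture(scope="session")
def probe_by_id(default_fixture):
    return {p.probe_id: p for p in default_fixture.probes}
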