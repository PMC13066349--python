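import pytest

from phylodi.io import PipelineConfig
from phylodi.pipeline import run_pipeline
from phylodi.simulate import generate_paperlike_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """The deterministic 19,504-gene synthetic universe with planted counts."""
    return generate_paperlike_fixture()


@pytest.fixture(scope="session")
def paper_result(paper_fixture):
    """Full pipeline output on the deterministic fixture."""
    fx = paper_fixture
    return run_pipeline(
        fx.universe,
        PipelineConfig(),
        hits=fx.hits,
        species_map=fx.species_map,
        sets=fx.sets,
        ladder=fx.ladder,
    )
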