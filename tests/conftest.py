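import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dagsynth import fixtures


@pytest.fixture(scope="session")
def bundle():
    """The two worked-example studies run through the full pipeline once."""
    return fixtures.paper_fixtures()


@pytest.fixture
def confounder_triangle():
    """Z -> X, Z -> Y, X -> Y: the textbook confounding structure."""
    from dagsynth.analysis import AnalysisGraph

    return AnalysisGraph.from_edges([("z", "x"), ("z", "y"), ("x", "y")])
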