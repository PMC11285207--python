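import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from flagseq import synthgen  # noqa: E402
from flagseq.librarydesign import TilingParams  # noqa: E402


@pytest.fixture(scope="session")
def template():
    return synthgen.default_template()


@pytest.fixture(scope="session")
def panel(template):
    return synthgen.generate_reference_panel(template, n_per_class=8, seed=11)


@pytest.fixture(scope="session")
def library(panel):
    tiles, annotations = synthgen.generate_library(
        panel, n_nonflagellin=60, tiling_params=TilingParams(), seed=12)
    return tiles, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
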