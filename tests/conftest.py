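import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from minmol.fixtures import build_fixture  # noqa: E402


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def bromobenzene():
    return build_fixture("bromobenzene_full")


@pytest.fixture
def bromobenzene_ph():
    return build_fixture("bromobenzene_ph")


@pytest.fixture
def sncl2():
    return build_fixture("sncl2_naive")
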