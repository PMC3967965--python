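import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from mirsnp.fixtures import tcf21_toy
from mirsnp.fold import default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def toy():
    """Synthetic TCF21-like transcript, rs12190287-style variant, miR-224."""
    return tcf21_toy()
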