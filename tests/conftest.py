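import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from islandcarbon import as_printed, calibrated


@pytest.fixture(scope="session")
def as_printed_config():
    return as_printed()


@pytest.fixture(scope="session")
def calibrated_config():
    # calibration re-verifies itself against the published budget on build
    return calibrated()
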