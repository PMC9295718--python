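import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracle.py importable

from ocbdyn import ParameterSet, RandomInputs, TimeGrid, simulate


@pytest.fixture(scope="session")
def default_mean_run():
    """Baseline scenario integrated in deterministic mean mode."""
    return simulate(ParameterSet(), TimeGrid(), RandomInputs(mode="mean"))


@pytest.fixture()
def mean_inputs():
    return RandomInputs(mode="mean")
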