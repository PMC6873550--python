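import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from smilesrnn.chemspace import FilterConfig, enumerate_toy_space


@pytest.fixture(scope="session")
def alkane_space():
    """{C, CC, CCC}: the forced saturated-acyclic enumeration."""
    return enumerate_toy_space(3, ["C"], FilterConfig(exclude_double_bonds=True))


@pytest.fixture(scope="session")
def tiny_space():
    """Default-filtered C/O space up to 4 heavy atoms (no rings possible)."""
    return enumerate_toy_space(4, ["C", "O"])


@pytest.fixture(scope="session")
def small_space():
    """Default-filtered C/N/O space up to 5 heavy atoms (~1500 molecules,
    includes five-membered rings and aromatics)."""
    return enumerate_toy_space(5, ["C", "N", "O"])
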