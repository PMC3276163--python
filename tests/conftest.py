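import numpy as np
import pytest

from arcsim import (
    ColonyGenotype,
    Haplotype,
    MarkerPanel,
    SimulationConfig,
    founder_haplotype,
)

MARKERS = ("194m6", "18m1", "28m6", "174m4")


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return MarkerPanel(MARKERS)


@pytest.fixture(scope="session")
def founders(panel):
    return {lbl: founder_haplotype(lbl, panel) for lbl in ("f", "r", "c", "d")}


@pytest.fixture
def ff(founders):
    return ColonyGenotype("ff", (founders["f"], founders["f"]))


@pytest.fixture
def fd(founders):
    return ColonyGenotype("fd", (founders["f"], founders["d"]))


@pytest.fixture
def rr(founders):
    return ColonyGenotype("rr", (founders["r"], founders["r"]))


@pytest.fixture
def recombinant_rf(panel, founders):
    """A haplotype with alr1 from r and alr2 (plus 174-region markers) from f."""
    h = Haplotype(
        "r+f",
        {"194m6": "r", "18m1": "r", "28m6": "f", "174m4": "f"},
        alr1_allele="r",
        alr2_allele="f",
    )
    return h


@pytest.fixture
def config():
    return SimulationConfig(seed=20260101, map_distances_cM=(12.2, 6.1, 12.2))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
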