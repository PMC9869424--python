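from pathlib import Path

import pytest

from baitforge.synthetic_data import (
    SimulationSpec,
    references_from_truth,
    simulate_reference_set,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def reference_set(small_spec):
    """(contigs, transcriptomes, truth) for the default small study."""
    return simulate_reference_set(small_spec)


@pytest.fixture(scope="session")
def planted_references(reference_set):
    contigs, _, truth = reference_set
    return references_from_truth(contigs, truth)
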