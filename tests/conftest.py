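import warnings

import pytest

from barcodedelim.alignment import Alignment, collapse_haplotypes
from barcodedelim.distances import DistanceModelConfig, distance_matrix
from barcodedelim.simulate import SimulationParams, generate_easy_dataset

warnings.filterwarnings("ignore", message="NJ produced")


def make_alignment(records, outgroup=()):
    ids = tuple(r[0] for r in records)
    seqs = tuple(r[1].upper() for r in records)
    return Alignment(ids=ids, seqs=seqs, length=len(seqs[0]), outgroup_ids=frozenset(outgroup))


@pytest.fixture(scope="session")
def easy_dataset():
    """A simulated dataset with a clear barcoding gap (ratio >= 5): the
    regime in which every delimiter is expected to recover the truth."""
    return generate_easy_dataset(SimulationParams(seed=1), min_gap_ratio=5.0)


@pytest.fixture(scope="session")
def easy_k2p(easy_dataset):
    return distance_matrix(easy_dataset.alignment, DistanceModelConfig(model="K2P"))


@pytest.fixture(scope="session")
def easy_reduced(easy_dataset):
    return collapse_haplotypes(easy_dataset.alignment)
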