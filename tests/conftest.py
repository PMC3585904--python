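import numpy as np
import pytest

from divergraft.data_io import build_clustered_alignment
from divergraft.parsimony import count_table
from divergraft.synthetic_data import paperlike_config, simulate_alignment


@pytest.fixture
def quartet_alignment():
    """Minimal 4-taxon clustered alignment: ((a,b),(c,d)) with {a,b}=A."""
    taxa = ["a", "b", "c", "d"]
    seqs = ["ACDA", "ACDA", "ASEA", "ASEA"]
    tree = "((a:1,b:1):1,(c:1,d:1):1);"
    clusters = {"a": "A", "b": "A", "c": "B", "d": "B"}
    return build_clustered_alignment((taxa, seqs), tree, clusters)


@pytest.fixture(scope="session")
def paperlike_dataset():
    """One paperlike simulated dataset with its planted truth and counts."""
    ca, truth = simulate_alignment(paperlike_config(seed=11))
    return ca, truth, count_table(ca)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
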