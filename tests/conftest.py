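import numpy as np
import pytest

import clockevol as ce


@pytest.fixture(scope="session")
def toy_alignment():
    """Three short in-frame sequences with known differences."""
    return ce.CodonAlignment(
        "toy",
        ("A", "B", "C"),
        ("ATGGCTAAA", "ATGGCCAAA", "ATGGCTAAG"),
    )


@pytest.fixture(scope="session")
def small_tree():
    return ce.tree_from_string("((A:0.1,B:0.1):0.05,C:0.15);")


@pytest.fixture(scope="session")
def sim_world():
    """A mid-sized simulated dataset shared by several slow-ish tests."""
    tree = ce.simulate_tree(8, 0.4, seed=11)
    spec = ce.spec_m0(0.3, 2.0)
    aln, labels = ce.simulate_codon_alignment(tree, spec, 200, seed=12)
    return tree, spec, aln, labels
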