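import numpy as np
import pytest

from coilgel.structure_io import (CrickParams, build_ideal_pentamer,
                                  example_sequence)


@pytest.fixture(scope="session")
def q_seq():
    """54-residue Q-like heptad sequence with the default register."""
    return example_sequence()


@pytest.fixture(scope="session")
def pentamer(q_seq):
    return build_ideal_pentamer(q_seq, CrickParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
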