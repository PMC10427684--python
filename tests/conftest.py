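import pytest

from delforge.chem_core import load_reaction_defs
from delforge.synthetic_data import generate_toy_design, make_truth


@pytest.fixture(scope="session")
def reactions():
    return load_reaction_defs()


@pytest.fixture(scope="session")
def toy_design():
    """2 skeletons x 3 capping BBs x 4 boronates, 2 null conditions."""
    return generate_toy_design(2, 3, 4, seed=0)


@pytest.fixture(scope="session")
def small_truth():
    """A small simulation truth with 5 planted 50x binders."""
    return make_truth(n_skel=2, n_caps=3, n_boronates=4, seed=1)
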