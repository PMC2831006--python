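import numpy as np
import pytest

from editscreen import conservation as cons
from editscreen import pipeline as pl
from editscreen.formats_io import read_newick


@pytest.fixture(scope="session")
def species_tree():
    return cons.default_species_tree()


@pytest.fixture(scope="session")
def parsimony_null(species_tree):
    return cons.ParsimonyNull(species_tree, cons.ConservationParams())


@pytest.fixture(scope="session")
def four_leaf_tree():
    return read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);", focal_species="A")


@pytest.fixture(scope="session")
def screen_fixture():
    return pl.make_screen_fixture(seed=0)


@pytest.fixture(scope="session")
def screen_run(screen_fixture):
    fx = screen_fixture
    explorative = pl.run_explorative_screen(fx.genome, fx.blocks, fx.tree)
    result = pl.run_refinement(
        fx.genome, fx.gene, explorative, fx.blocks, fx.tree, fx.ests, fx.snps
    )
    return fx, explorative, result


@pytest.fixture
def rng():
    return np.random.default_rng(0)
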