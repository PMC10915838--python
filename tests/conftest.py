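import numpy as np
import pytest

from gencat.benchmark import (
    LandscapeParams,
    default_panel,
    make_benchmark_library,
    make_landscape,
)
from gencat.fragments import CatalystTemplate, Fragment, FragmentLibrary


@pytest.fixture(scope="session")
def toy_library() -> FragmentLibrary:
    """One 2-slot template over |R1|=3, |R2|=4: a 12-candidate space."""
    fragments = [
        Fragment("f1", "F", "R1"),
        Fragment("f2", "Cl", "R1"),
        Fragment("f3", "C", "R1"),
        Fragment("g1", "Br", "R2"),
        Fragment("g2", "OC", "R2"),
        Fragment("g3", "N", "R2"),
        Fragment("g4", "CC", "R2"),
    ]
    template = CatalystTemplate(
        "t1", "urea", "O=C(N{a})N{b}", (("a", "R1"), ("b", "R2"))
    )
    return FragmentLibrary([template], fragments)


@pytest.fixture(scope="session")
def symmetric_library() -> FragmentLibrary:
    """A CPA-like template whose two R3 slots must carry the same fragment."""
    fragments = [Fragment(f"s{i}", smi, "R3") for i, smi in
                 enumerate(["F", "Cl", "C", "OC", "Br"])]
    template = CatalystTemplate(
        "cpa", "CPA-BINOL",
        "O=P1(O)Oc2ccc({p})cc2-c2cc({q})ccc2O1",
        (("p", "R3"), ("q", "R3")),
        symmetric_groups=(("p", "q"),),
    )
    return FragmentLibrary([template], fragments)


@pytest.fixture(scope="session")
def landscape():
    """The default 180-candidate benchmark landscape."""
    return make_landscape(1)


@pytest.fixture(scope="session")
def panel(landscape):
    return default_panel(landscape, k=8, seed=0)


@pytest.fixture(scope="session")
def noise_free_landscape():
    return make_landscape(
        1, LandscapeParams(state_noise=0.0, noise_sigma_ddg=0.0,
                           noise_sigma_descriptor=0.0, interaction_density=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
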