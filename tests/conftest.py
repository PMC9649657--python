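import numpy as np
import pytest

import masfold as mf
from masfold.sampling import AnnealingSchedule, CoolingSpec


@pytest.fixture(scope="session")
def fixture_a():
    """The standard synthetic fixture: 30-residue helix-loop-helix chain,
    glucose_16 peak list, torsions, 4-copy helical lattice and its 8 A map."""
    return mf.make_fixture_a()


@pytest.fixture(scope="session")
def fixture_restraints(fixture_a):
    return mf.peaks_to_restraints(fixture_a["peaks"])


@pytest.fixture(scope="session")
def toy_fold():
    st, truth = mf.make_toy_fold(30, "helix-loop-helix", seed=7)
    return st


@pytest.fixture()
def short_schedule():
    """A desk-scale annealing schedule for tests: one brief 3000 K stage and
    an 8-step cooling ladder."""
    return AnnealingSchedule(
        high_t_stages=[(3000.0, 0.2, 2000)],
        cooling=CoolingSpec(3000.0, 25.0, 425.0, 0.1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
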