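import numpy as np
import pytest

from wormstates import Perturbation, SyntheticConfig, simulate_strains
from wormstates.binning import ResponsibilityMatrix


def one_hot(sequence, k):
    """One-hot responsibility rows from an integer state sequence."""
    seq = np.asarray(sequence, int)
    r = np.zeros((len(seq), k))
    r[np.arange(len(seq)), seq] = 1.0
    return ResponsibilityMatrix(values=r, worm_id="w")


@pytest.fixture(scope="session")
def small_collection():
    """A small clean 3-strain collection used across modules."""
    config = SyntheticConfig(
        n_strains=3,
        worms_per_strain=5,
        frames_per_worm=600,
        n_attractors=4,
        seed=11,
    )
    return simulate_strains(config)


@pytest.fixture(scope="session")
def two_usage_strains():
    """Two strains with clearly distinct state usage (reweight mutant)."""
    config = SyntheticConfig(
        n_strains=2,
        worms_per_strain=6,
        frames_per_worm=800,
        n_attractors=4,
        seed=7,
    )
    return simulate_strains(
        config, {"MT001": Perturbation(kind="reweight", strength=1.5)}
    )
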