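import numpy as np
import pytest

from smallcrt.simulator import Scenario, generate_trial
from smallcrt.trial_data import TrialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_six_clusters():
    """Six clusters of size 10; control events 1,2,3; intervention 4,5,6."""
    return TrialDataset.from_arrays(
        arm=[0, 0, 0, 1, 1, 1],
        events=[1, 2, 3, 4, 5, 6],
        size=[10] * 6,
    )


@pytest.fixture
def medium_trial(rng):
    """A well-behaved simulated trial: 30 clusters, mean size 50, OR = 2."""
    scen = Scenario(
        n_clusters=30, mean_size=50, cv_size=0.5, control_prevalence=0.3,
        icc=0.05, effect=2.0, effect_distribution="normal",
    )
    return generate_trial(scen, rng)


def make_trial(seed: int, **kwargs) -> TrialDataset:
    defaults = dict(
        n_clusters=12, mean_size=30, cv_size=0.5, control_prevalence=0.3,
        icc=0.05, effect=2.0, effect_distribution="normal",
    )
    defaults.update(kwargs)
    return generate_trial(Scenario(**defaults), np.random.default_rng(seed))
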