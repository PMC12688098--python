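import numpy as np
import pytest

from attune import demos, environment as env, irl


@pytest.fixture(scope="session")
def original():
    return env.builtin_layout("original")


@pytest.fixture(scope="session")
def all_layouts():
    return {name: env.builtin_layout(name) for name in env.BUILTIN_LAYOUTS}


@pytest.fixture(scope="session")
def kitchen(original):
    return irl.KitchenMdp(original)


@pytest.fixture(scope="session")
def cohort():
    """The full study-scale synthetic cohort (110 latino + 190 white)."""
    return demos.generate_cohort(demos.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def trained_models(cohort, kitchen):
    """Reward models trained on the four trace datasets of the cohort."""
    models = {}
    for name in ("altruistic", "non_altruistic", "latino", "white"):
        dset = kitchen.traces_to_demos(cohort.datasets[name])
        net, _ = irl.train_irl(dset, kitchen.mdp, irl.IRLHyper(n_iters=200), seed=0)
        models[name] = net
    return models


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
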