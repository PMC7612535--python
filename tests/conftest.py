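import pytest

import heatmort as hm

# One shared synthetic study (two regions, 10 training summers + 1 target
# summer) and a fitted model, reused across test modules to keep the suite
# fast.  Everything is deterministic given the seed.

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    cfg = hm.default_config(n_summers=11, region_names=("North", "South"), seed=STUDY_SEED)
    return hm.simulate_study(cfg)


@pytest.fixture(scope="session")
def north(study):
    return study.regions["North"]


@pytest.fixture(scope="session")
def fitted_model(north):
    """DLNM fitted on the ten training summers (2001–2010) of one region."""
    train = north.deaths.loc[:"2010-12-31"]
    return hm.DLNMHeatModel().fit(north.temperatures, train)


@pytest.fixture(scope="session")
def target_deaths(north):
    start, end = hm.summer_span(2011)
    return north.deaths.loc[start:end]
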