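import pytest

import poregraph as pg

#: the two canonical conduction cycles: two-step association/dissociation
#: (outer ion leaves first) and one-step knock-on (fourth ion pushes)
AD_SCRIPT = [
    "K:0:2:4", "K:0:1:3", "K:1:3", "K:1:2", "K:0:2", "K:0:2:6", "K:0:2:5", "K:0:2:4",
]
KO_SCRIPT = [
    "K:0:2:4", "K:0:2:4:6", "K:0:2:4:5", "K:0:1:3:5", "K:1:3:5", "K:1:3:4",
    "K:1:2:4", "K:0:2:4",
]


@pytest.fixture(scope="session")
def ad_traj():
    return pg.scripted_trajectory(AD_SCRIPT)


@pytest.fixture(scope="session")
def ko_traj():
    return pg.scripted_trajectory(KO_SCRIPT)


@pytest.fixture(scope="session")
def site_map():
    return pg.SiteMap()


@pytest.fixture(scope="session")
def kmc_traj():
    """A moderate simulated trajectory at reference conditions."""
    return pg.simulate_hopping(pg.KMCParams(duration_ns=200.0, seed=11))
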