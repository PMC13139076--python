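import pytest

import zonetox as zt
from zonetox.config import RunConfig

#: lattice size used for whole-lobule simulation tests: small enough to run
#: the full patient horizons quickly, large enough for three populated zones
TEST_N_CELLS = 60


@pytest.fixture(scope="session")
def default_lattice():
    return zt.build_lattice()


@pytest.fixture(scope="session")
def small_lattice():
    return zt.build_lattice(TEST_N_CELLS)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(n_cells=TEST_N_CELLS)


@pytest.fixture(scope="session")
def patients():
    return zt.patient_fixtures()


@pytest.fixture(scope="session")
def baseline_results(patients, small_lattice, small_config):
    """Full-horizon baseline lobule runs for all four patients."""
    out = {}
    for pat in patients:
        out[pat.id] = zt.simulate_case(
            pat, zt.ZonationSpec("H1", 0.0), small_config,
            lattice=small_lattice)
    return out


@pytest.fixture(scope="session")
def zonated_d_results(patients, small_lattice, small_config):
    """Patient D at 80% zonation for the directional hypotheses."""
    d = patients[3]
    out = {}
    for hyp in ("H1", "H3", "H4", "H5"):
        out[hyp] = zt.simulate_case(
            d, zt.ZonationSpec(hyp, 0.8), small_config,
            lattice=small_lattice)
    return out


def necrosed_tally(result, lattice):
    """Zone necrosed counts at the time of maximum necrosis."""
    _, idx = zt.time_of_max_necrosis(result.labels, result.t)
    return zt.tally_zones(result.labels[:, idx], lattice)[:, 2]
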