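import numpy as np
import pytest

from gradedform.calibrate import fit_grm, standard_errors
from gradedform.grm import ItemBank, ItemParameters, ThetaGrid
from gradedform.simulate import promis_bank_fixture, sample_theta, simulate_responses


@pytest.fixture(scope="session")
def fixture():
    """Packaged published 51-item calibration with flags, map and forms."""
    return promis_bank_fixture()


@pytest.fixture(scope="session")
def sf1_bank(fixture):
    return fixture.bank.subset(fixture.sf1_items)


@pytest.fixture(scope="session")
def sf2_bank(fixture):
    return fixture.bank.subset(fixture.sf2_items)


@pytest.fixture
def toy_item():
    return ItemParameters(item_id="toy", slope=2.0, thresholds=np.array([-1.0, 0.0, 1.0, 2.0]))


@pytest.fixture
def grid():
    return ThetaGrid.normal()


def make_bank(slopes, thresholds_list, prefix="it"):
    return ItemBank(items=[
        ItemParameters(item_id=f"{prefix}{k + 1}", slope=a, thresholds=np.asarray(b, float))
        for k, (a, b) in enumerate(zip(slopes, thresholds_list))
    ])


@pytest.fixture(scope="session")
def toy_bank5():
    """Small 5-item bank with spread parameters, used by scoring/SE tests."""
    rng = np.random.default_rng(7)
    slopes = rng.uniform(1.2, 3.0, 5)
    thresholds = [np.sort(rng.uniform(-2, 2, 4)) for _ in range(5)]
    return make_bank(slopes, thresholds)


@pytest.fixture(scope="session")
def wellfit(sf1_bank):
    """Session-shared well-specified calibration: 10 items, n=2000, complete.

    Returned as (generating bank, responses, fitted CalibrationResult with
    standard errors)."""
    theta = sample_theta(2000, seed=301)
    resp = simulate_responses(sf1_bank, theta, missing_rate=0.0, seed=302)
    res = fit_grm(resp)
    standard_errors(res, resp)
    return sf1_bank, resp, res
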