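import numpy as np
import pytest

from corticode import PopulationRateModel, build_population, calibrate_intensity_slope
from corticode.report import DELTA_F_HZ, DELTA_L_DB, standard_model


@pytest.fixture(scope="session")
def small_model() -> PopulationRateModel:
    """A reduced population (n=120) with the standard parameters."""
    return standard_model(n=120)


@pytest.fixture(scope="session")
def standard_analysis():
    """The full-size (n=1700) frequency and intensity analyses.

    Session-scoped because the 1700x1700 solves dominate the suite's
    runtime; results objects are immutable.
    """
    model25 = standard_model()
    model0 = model25.with_rho(0.0)
    freq25 = model25.fit(task="frequency", delta_x=DELTA_F_HZ)
    freq0 = model0.fit(task="frequency", delta_x=DELTA_F_HZ)
    cal = calibrate_intensity_slope(model25, delta_l_db=DELTA_L_DB, target_dprime=1.0)
    return {
        "model25": model25,
        "model0": model0,
        "freq25": freq25,
        "freq0": freq0,
        "calibration": cal,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
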