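import numpy as np
import pytest

from dyncest import bmc, schedule as sched
from dyncest.schedule import TimingParams
from dyncest.synth import DynamicSeries


@pytest.fixture(scope="session")
def field():
    return bmc.FieldParams()


@pytest.fixture(scope="session")
def water():
    return bmc.water_pool()


@pytest.fixture(scope="session")
def thiol():
    return bmc.thiol_pool(fraction=2e-4)


@pytest.fixture(scope="session")
def amide():
    return bmc.amide_pool(fraction=3e-4)


@pytest.fixture(scope="session")
def short_train():
    """Reduced train (20 pulses) for fast unit tests of spectral shape."""
    return bmc.SaturationTrain(bmc.SaturationPulse(), n_pulses=20)


@pytest.fixture(scope="session")
def timing():
    return TimingParams()


def make_series(schedule, z_of_entry, grid=8, base=2.0):
    """Small DynamicSeries whose images are base * z_of_entry(entry, t_min).

    The liver mask covers the central block of the grid; used to exercise the
    quantification chain with hand-chosen signal laws.
    """
    liver = np.zeros((grid, grid), bool)
    liver[grid // 4: -grid // 4, grid // 4: -grid // 4] = True
    images = np.stack([
        np.full((grid, grid), base * z_of_entry(e, e.t_mid_s / 60.0))
        for e in schedule.entries
    ])
    return DynamicSeries(images, list(schedule.entries),
                         {"liver": liver, "background": ~liver}, schedule.timing)


@pytest.fixture
def tiny_fl1(timing):
    return sched.build_fl1(timing, n_dummy=2, n_cycles=6)
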