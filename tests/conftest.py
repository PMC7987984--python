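import numpy as np
import pytest

import fertcurves as fc
from fertcurves import nfhs4


AGES = np.arange(15, 50)


def noiseless_schedule(family: str, params: dict) -> fc.FertilitySchedule:
    """Exact model curve as a schedule (no sampling noise)."""
    cfg = fc.SimulationConfig(family=family, params=params,
                              noise=fc.GaussianNoise(0.0), seed=0)
    return fc.generate_schedule(cfg)


@pytest.fixture(scope="session")
def india_modified_gompertz():
    return nfhs4.MODIFIED_GOMPERTZ_ESTIMATES["India"]


@pytest.fixture(scope="session")
def india_modified_pk():
    return nfhs4.MODIFIED_PK_ESTIMATES["India"]


@pytest.fixture(scope="session")
def india_schedule(india_modified_gompertz):
    """A realistic noiseless India-like schedule (Modified Gompertz curve)."""
    return noiseless_schedule("modified_gompertz", india_modified_gompertz)


@pytest.fixture(scope="session")
def noisy_india_schedule(india_modified_gompertz):
    cfg = fc.SimulationConfig(
        family="modified_gompertz", params=india_modified_gompertz,
        noise=fc.GaussianNoise(0.002), seed=42)
    return fc.generate_schedule(cfg)
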