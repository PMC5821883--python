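import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from digiwell.chip import NEGATIVE, POSITIVE, ChipRun, WellRecord, default_well_id
from digiwell.simulate import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def config():
    return SimulationConfig()


def make_run(positive_cqs, n_partitions=2500, fail_wells=0, metadata=None):
    """A chip with the given positive-well Cq values, the rest negative."""
    grid = int(np.sqrt(n_partitions))
    wells = []
    cqs = list(positive_cqs)
    for i in range(n_partitions):
        r, c = divmod(i, grid)
        wid = default_well_id(r, c)
        if i < len(cqs):
            wells.append(WellRecord(wid, r, c, float(cqs[i]), POSITIVE))
        elif i < len(cqs) + fail_wells:
            wells.append(WellRecord(wid, r, c, None, "fail"))
        else:
            wells.append(WellRecord(wid, r, c, None, NEGATIVE))
    kwargs = {"metadata": metadata} if metadata is not None else {}
    return ChipRun(wells=wells, n_partitions=n_partitions, **kwargs)


@pytest.fixture
def run_factory():
    return make_run
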