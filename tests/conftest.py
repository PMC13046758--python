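import numpy as np
import pandas as pd
import pytest

from heattract.synthetic import TruthScenario, make_truth_fields
from heattract.timegrid import ReferenceGrid


@pytest.fixture(scope="session")
def default_scenario() -> TruthScenario:
    return TruthScenario(seed=7)


@pytest.fixture(scope="session")
def truth(default_scenario):
    return make_truth_fields(default_scenario)


@pytest.fixture(scope="session")
def small_scenario() -> TruthScenario:
    """Reduced domain for end-to-end pipeline tests."""
    return TruthScenario(seed=11, nx=10, ny=10, n_days=2, solar_nx=4, solar_ny=4,
                         n_tracts_x=2, n_tracts_y=2, n_stations=8)


def make_grid(lat, lon, elevation=None, cell_ids=None, tol=np.inf) -> ReferenceGrid:
    """Grid helper for tests; spacing regularity unchecked unless ``tol`` given."""
    lat = np.asarray(lat, dtype=float)
    n = len(lat)
    return ReferenceGrid(
        pd.DataFrame(
            {
                "cell_id": np.arange(n) if cell_ids is None else cell_ids,
                "lat": lat,
                "lon": np.asarray(lon, dtype=float),
                "elevation": np.zeros(n) if elevation is None else elevation,
            }
        ),
        spacing_tolerance=tol,
    )
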