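import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

import foraykit as fk
from foraykit.simulate import SimulationConfig, simulate_population


@pytest.fixture
def unit_square() -> Polygon:
    return Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def l_shape() -> Polygon:
    # concave L: unit square with the top-right quadrant removed
    return Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])


@pytest.fixture
def straight_line() -> LineString:
    return LineString([(0, 0), (10_000, 0)])


def make_fixes(times, xy, individual_id="B01", hdop=1.0, sats=8, tz="Europe/Oslo"):
    """Hand-build a labelled fix table for unit tests."""
    ts = pd.to_datetime(times)
    if ts.tz is None:
        ts = ts.tz_localize(tz)
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": ts,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "hdop": hdop,
            "n_satellites": sats,
            "medium": "unset",
            "movement_type": "unset",
        }
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated dataset shared by io/pipeline tests."""
    cfg = SimulationConfig(
        seed=42, n_territories=5, territory_length_km=2.0, n_nights=6,
        foray=fk.ForayParams(p_per_night=0.25, p_never=0.0),
    )
    statuses = [(f"B{i:02d}", "dominant" if i <= 6 else "subordinate") for i in range(1, 9)]
    return simulate_population(cfg, statuses=statuses)
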