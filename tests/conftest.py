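import numpy as np
import pandas as pd
import pytest

from soilgaps import SensorMeta, build_time_grid


@pytest.fixture
def small_grid():
    return build_time_grid(
        "2007-01-01 00:00", "2007-01-05 00:00", "2007-01-03 00:00", 120, 150
    )


@pytest.fixture
def toy_meta():
    return [
        SensorMeta("Stipa_1", "Stipa", 1),
        SensorMeta("Stipa_2", "Stipa", 2),
        SensorMeta("BSCl_1", "BSCl", 1),
    ]


@pytest.fixture
def toy_table(small_grid, toy_meta):
    """3 sensors on a 2-cadence grid with a few missing cells."""
    rng = np.random.default_rng(42)
    base = 0.1 + 0.05 * np.sin(np.linspace(0, 4, len(small_grid)))
    table = pd.DataFrame(
        {
            "Stipa_1": base + rng.normal(0, 0.004, len(small_grid)),
            "Stipa_2": 0.9 * base + 0.01 + rng.normal(0, 0.004, len(small_grid)),
            "BSCl_1": 0.6 * base + rng.normal(0, 0.004, len(small_grid)),
        },
        index=small_grid,
    )
    table.iloc[3, 0] = np.nan
    table.iloc[7, 1] = np.nan
    table.iloc[7, 2] = np.nan
    return table


def random_network(rng, n_sensors=None, n_timestamps=None, p_missing=0.35):
    """Random small network for oracle comparisons.

    Returns (table, meta, values, microsites) where values/microsites are
    plain-python structures for the brute-force oracles.
    """
    from soilgaps.io import MICROSITES

    n_sensors = n_sensors or int(rng.integers(3, 9))
    n_timestamps = n_timestamps or int(rng.integers(30, 201))
    grid = pd.date_range("2010-01-01", periods=n_timestamps, freq="120min")
    grid.name = "timestamp"
    sites = rng.choice(MICROSITES, size=n_sensors)
    meta, cols = [], {}
    base = rng.normal(0.15, 0.05, n_timestamps).cumsum() * 0.01 + 0.2
    for i in range(n_sensors):
        sid = f"s{i}"
        meta.append(SensorMeta(sid, str(sites[i]), 1))
        series = (
            base * rng.uniform(0.5, 1.5)
            + rng.normal(0, 0.02, n_timestamps)
            + rng.uniform(-0.05, 0.05)
        )
        series[rng.random(n_timestamps) < p_missing] = np.nan
        cols[sid] = series
    table = pd.DataFrame(cols, index=grid)
    values = {
        sid: [None if np.isnan(v) else float(v) for v in col]
        for sid, col in table.items()
    }
    microsites = {m.sensor_id: m.microsite for m in meta}
    return table, meta, values, microsites
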