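import numpy as np
import pandas as pd
import pytest

from aqnet import AssociationNetwork, PanelSpec, SeasonalProfile, simulate_panel
from aqnet.synthetic import PlantedNetwork, planted_matching


def make_network(adj, nodes=None, pollutant="AQI"):
    adj = np.asarray(adj, dtype=int)
    nodes = nodes or [chr(ord("A") + i) for i in range(adj.shape[0])]
    return AssociationNetwork(nodes=list(nodes), adjacency=adj, pollutant=pollutant)


def random_adjacency(n, p, rng):
    adj = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(adj, 0)
    return adj


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_panel():
    """6 cities, one planted pair, mild seasonality, some missing cells."""
    spec = PanelSpec(n_cities=6, n_periods=240, seed=5)
    net = planted_matching(6, 2, seed=3, coupling=0.8)
    return simulate_panel(
        spec, net, SeasonalProfile(amplitude=5.0), missing_rate=0.01
    ), net


@pytest.fixture(scope="session")
def aligned_pair_series():
    """Strongly coupled (x -> y) stationary pair, T=879."""
    g = np.random.default_rng(77)
    t = 879
    x = np.empty(t)
    y = np.empty(t)
    ex, ey = g.normal(size=t), g.normal(size=t)
    x[0], y[0] = ex[0], ey[0]
    for i in range(1, t):
        x[i] = 0.5 * x[i - 1] + ex[i]
        y[i] = 0.5 * y[i - 1] + 0.8 * x[i - 1] + ey[i]
    return x, y


def series_panel(values: dict[str, list[float]], pollutant="AQI",
                 start="2015-01-06") -> pd.DataFrame:
    """Build a tiny long-format panel from explicit per-city sequences."""
    frames = []
    for city, vals in values.items():
        dates = pd.date_range(start, periods=len(vals), freq="D")
        frames.append(pd.DataFrame(
            {"city": city, "date": dates, "pollutant": pollutant, "value": vals}
        ))
    return pd.concat(frames, ignore_index=True)
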