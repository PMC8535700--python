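"""Synthetic multi-city pollutant panels with known ground truth.

Emulates a daily air-quality panel (one AQI series plus individual
pollutant series per city) in which inter-city transmission follows a
*planted* directed causal network: city i drives city j with a fixed lag
and coupling strength.  Because the true network, seasonality and
cross-pollutant weights are known, every downstream stage (stationarity
screening, pairwise Granger tests, network statistics, blockmodelling,
QAP regression) can be validated against ground truth without any
external data.

The AQI anomaly process is a VAR: for anomaly vector ``a_t``,

    a_t = phi * a_{t-1} + coupling * W' a_{t-lag} + eps_t,

where ``W`` is the planted adjacency (``W[i, j] = 1`` means i drives j)
and ``eps_t`` is i.i.d. Gaussian.  The observed AQI adds a baseline and
an annual sinusoid peaking in winter.  Non-AQI pollutants are noisy
affine transforms of the AQI anomaly plus an idiosyncratic AR(1)
component, with per-pollutant weights controlling how faithfully each
pollutant network mirrors the AQI network.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_POLLUTANTS",
    "DEFAULT_POLLUTANT_WEIGHTS",
    "PanelSpec",
    "PlantedNetwork",
    "SeasonalProfile",
    "simulate_panel",
    "planted_blocks",
    "planted_matching",
    "write_ground_truth",
]

#: Series simulated per city: the composite index first, then the six
#: individual pollutants.
DEFAULT_POLLUTANTS = ("AQI", "PM2.5", "PM10", "SO2", "CO", "NO2", "O3")

#: How strongly each pollutant tracks the AQI anomaly.  Ordered so that
#: fine particulates dominate the cross-pollutant structure (PM2.5
#: largest, SO2 smallest), which is the ordering a QAP regression of the
#: AQI network on the pollutant networks should recover.
DEFAULT_POLLUTANT_WEIGHTS = {
    "PM2.5": 0.90,
    "PM10": 0.70,
    "NO2": 0.55,
    "O3": 0.45,
    "CO": 0.40,
    "SO2": 0.30,
}


@dataclass(frozen=True)
class PanelSpec:
    """Dimensions and identity of a simulated panel.

    Defaults mirror a 35-city, 879-day daily panel starting 6 Jan 2015
    with the seven standard series.
    """

    n_cities: int = 35
    n_periods: int = 879
    pollutants: tuple[str, ...] = DEFAULT_POLLUTANTS
    start_date: date = date(2015, 1, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 2:
            raise ValueError("n_cities must be >= 2")
        if self.n_periods < 50:
            raise ValueError("n_periods must be >= 50")
        if not self.pollutants:
            raise ValueError("pollutants must be non-empty")
        if len(set(self.pollutants)) != len(self.pollutants):
            raise ValueError("pollutants must be unique")

    @property
    def cities(self) -> list[str]:
        width = len(str(self.n_cities - 1))
        return [f"city{i:0{width}d}" for i in range(self.n_cities)]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_periods, freq="D")


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground-truth directed causal network among cities.

    ``adjacency[i, j] = 1`` means city i drives city j at lag ``lag``
    with coefficient ``coupling``.
    """

    adjacency: np.ndarray
    lag: int = 1
    coupling: float = 0.5
    block_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.diag(a).any():
            raise ValueError("adjacency must have a zero diagonal")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        object.__setattr__(self, "adjacency", a.astype(int))

    @property
    def n_cities(self) -> int:
        return self.adjacency.shape[0]

    def transition_matrices(self, ar_coef: float) -> list[np.ndarray]:
        """Lag-polynomial coefficient matrices Phi_1..Phi_lag of the
        anomaly VAR (Phi_k maps a_{t-k} to a_t)."""
        n = self.n_cities
        mats = [np.zeros((n, n)) for _ in range(self.lag)]
        mats[0] += ar_coef * np.eye(n)
        mats[self.lag - 1] += self.coupling * self.adjacency.T
        return mats

    def spectral_radius(self, ar_coef: float) -> float:
        """Spectral radius of the VAR companion matrix; < 1 iff the
        anomaly process is stationary."""
        n, L = self.n_cities, self.lag
        companion = np.zeros((n * L, n * L))
        for k, phi in enumerate(self.transition_matrices(ar_coef)):
            companion[:n, k * n : (k + 1) * n] = phi
        if L > 1:
            companion[n:, : n * (L - 1)] = np.eye(n * (L - 1))
        return float(np.abs(np.linalg.eigvals(companion)).max())


@dataclass(frozen=True)
class SeasonalProfile:
    """Annual sinusoid peaking in winter.

    ``phase`` is the day-of-year of the winter maximum (default 15 ==
    mid January); ``amplitude = 0`` disables seasonality.
    """

    amplitude: float = 20.0
    phase: int = 15
    baseline: float = 80.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def component(self, dates: pd.DatetimeIndex) -> np.ndarray:
        doy = dates.dayofyear.to_numpy(dtype=float)
        return self.baseline + self.amplitude * np.cos(
            2.0 * np.pi * (doy - self.phase) / 365.25
        )


def _simulate_anomalies(
    spec: PanelSpec,
    net: PlantedNetwork,
    ar_coef: float,
    noise_sd: float,
    rng: np.random.Generator,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate the stationary AQI anomaly VAR, shape (T, n_cities)."""
    n, L = net.n_cities, net.lag
    phis = net.transition_matrices(ar_coef)
    total = spec.n_periods + burn_in + L
    a = np.zeros((total, n))
    eps = rng.normal(0.0, noise_sd, size=(total, n))
    for t in range(L, total):
        acc = eps[t]
        for k, phi in enumerate(phis, start=1):
            acc = acc + phi @ a[t - k]
        a[t] = acc
    return a[-spec.n_periods :]


def simulate_panel(
    spec: PanelSpec,
    net: PlantedNetwork,
    season: SeasonalProfile | None = None,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    ar_coef: float = 0.5,
    pollutant_weights: dict[str, float] | None = None,
    idio_sd: float = 1.0,
    idio_ar: float = 0.3,
) -> pd.DataFrame:
    """Simulate a long-format pollutant panel.

    Parameters
    ----------
    spec
        Panel dimensions, labels and seed.
    net
        Planted directed causal network among cities.
    season
        Winter-peaked annual profile added to AQI (and, scaled by the
        pollutant weight, to each pollutant).  ``None`` uses defaults.
    noise_sd
        Innovation standard deviation of the AQI anomaly VAR (> 0).
    missing_rate
        Fraction of cells set to NaN, completely at random, never at
        the first or last observation of a series.
    ar_coef
        Own-lag AR(1) coefficient of each city's anomaly.
    pollutant_weights
        Loading of each non-AQI pollutant on the AQI anomaly.
    idio_sd, idio_ar
        Scale and AR(1) coefficient of each pollutant's idiosyncratic
        component.

    Returns
    -------
    DataFrame with columns ``city, date, pollutant, value``, sorted.

    Raises
    ------
    ValueError
        If the planted coefficients imply a non-stationary VAR
        (companion spectral radius >= 1) or arguments are out of range.
    """
    if season is None:
        season = SeasonalProfile()
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if net.n_cities != spec.n_cities:
        raise ValueError(
            f"planted network has {net.n_cities} cities, spec has {spec.n_cities}"
        )
    rho = net.spectral_radius(ar_coef)
    if rho >= 1.0:
        raise ValueError(
            f"unstable generator: VAR companion spectral radius {rho:.3f} >= 1 "
            f"(coupling={net.coupling}, ar_coef={ar_coef}); "
            "reduce coupling, ar_coef or network density"
        )
    weights = dict(DEFAULT_POLLUTANT_WEIGHTS if pollutant_weights is None
                   else pollutant_weights)

    rng = np.random.default_rng(spec.seed)
    anomalies = _simulate_anomalies(spec, net, ar_coef, noise_sd, rng)
    seasonal = season.component(spec.dates)

    frames: dict[str, np.ndarray] = {}
    for pol in spec.pollutants:
        if pol == "AQI":
            frames[pol] = seasonal[:, None] + anomalies
            continue
        w = weights.get(pol, 0.5)
        idio = np.empty_like(anomalies)
        e = rng.normal(0.0, idio_sd, size=anomalies.shape)
        idio[0] = e[0]
        for t in range(1, idio.shape[0]):
            idio[t] = idio_ar * idio[t - 1] + e[t]
        frames[pol] = w * (seasonal[:, None] + anomalies) + idio

    panel = pd.concat(
        [
            pd.DataFrame(
                {
                    "city": np.repeat(spec.cities, spec.n_periods),
                    "date": np.tile(spec.dates, spec.n_cities),
                    "pollutant": pol,
                    "value": frames[pol].T.ravel(),
                }
            )
            for pol in spec.pollutants
        ],
        ignore_index=True,
    )

    if missing_rate > 0:
        n_cells = len(panel)
        n_missing = int(np.floor(missing_rate * n_cells))
        # endpoints of each (city, pollutant) series are never removed so
        # two-sided neighbour imputation is always applicable
        t_index = np.tile(np.arange(spec.n_periods), spec.n_cities * len(spec.pollutants))
        eligible = np.flatnonzero((t_index != 0) & (t_index != spec.n_periods - 1))
        drop = rng.choice(eligible, size=n_missing, replace=False)
        panel.loc[drop, "value"] = np.nan

    panel = panel.sort_values(["pollutant", "city", "date"], ignore_index=True)
    return panel[["city", "date", "pollutant", "value"]]


def planted_blocks(
    n_cities: int,
    n_blocks: int,
    p_within: float,
    p_between: float,
    seed: int = 0,
    lag: int = 1,
    coupling: float = 0.5,
) -> PlantedNetwork:
    """Stochastic-block-model adjacency with recorded true labels.

    Blocks have equal size ``n_cities // n_blocks``; any remainder is
    assigned to the last block.  Within-block ordered pairs receive an
    edge with probability ``p_within``, between-block pairs with
    ``p_between`` (``p_within > p_between`` required so the planted
    partition is identifiable).
    """
    if not (0 <= p_between <= 1 and 0 <= p_within <= 1):
        raise ValueError("edge probabilities must be in [0, 1]")
    if p_within <= p_between:
        raise ValueError("p_within must exceed p_between")
    if n_blocks < 1 or n_blocks > n_cities:
        raise ValueError("n_blocks must be in [1, n_cities]")
    rng = np.random.default_rng(seed)
    size = n_cities // n_blocks
    labels = np.minimum(np.arange(n_cities) // size, n_blocks - 1)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, p_within, p_between)
    adj = (rng.random((n_cities, n_cities)) < p).astype(int)
    np.fill_diagonal(adj, 0)
    return PlantedNetwork(adj, lag=lag, coupling=coupling, block_labels=labels)


def planted_matching(
    n_cities: int,
    n_edges: int,
    seed: int = 0,
    lag: int = 1,
    coupling: float = 0.8,
) -> PlantedNetwork:
    """Random directed matching: ``n_edges`` disjoint source->sink pairs.

    Each city participates in at most one edge, so the planted graph has
    no two-step paths and no common drivers.  This makes it the
    appropriate ground truth for edge-recovery benchmarks: pairwise
    Granger tests genuinely detect indirect transmission, so sensitivity
    and false-positive rates are only well defined against a confound-free
    planted network.
    """
    if n_edges < 1 or 2 * n_edges > n_cities:
        raise ValueError("need 2 * n_edges <= n_cities")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cities)
    adj = np.zeros((n_cities, n_cities), dtype=int)
    for k in range(n_edges):
        adj[order[2 * k], order[2 * k + 1]] = 1
    return PlantedNetwork(adj, lag=lag, coupling=coupling)


def write_ground_truth(
    path: str | Path,
    spec: PanelSpec,
    net: PlantedNetwork,
    season: SeasonalProfile,
    **params,
) -> None:
    """Persist the generator's ground truth: adjacency as a CSV matrix
    and all generator parameters as JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cities = spec.cities
    pd.DataFrame(net.adjacency, index=cities, columns=cities).to_csv(
        path / "planted_adjacency.csv"
    )
    meta = {
        "spec": {**dataclasses.asdict(spec), "start_date": spec.start_date.isoformat(),
                 "pollutants": list(spec.pollutants)},
        "network": {"lag": net.lag, "coupling": net.coupling,
                    "n_edges": int(net.adjacency.sum())},
        "season": dataclasses.asdict(season),
        **params,
    }
    if net.block_labels is not None:
        meta["network"]["block_labels"] = [int(x) for x in net.block_labels]
    (path / "generator_params.json").write_text(json.dumps(meta, indent=2))
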