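"""Panel preprocessing: imputation, half-year summaries, stationarity.

Granger tests require stationary inputs, so every (city, pollutant)
series is screened with the augmented Dickey-Fuller (ADF) test and
first-differenced until it passes (up to ``max_diffs``).  Missing daily
observations are filled with the mean of the nearest valid observations
on either side of the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "PANEL_COLUMNS",
    "validate_panel",
    "impute_missing",
    "half_year_means",
    "ensure_stationary",
    "StationaryPanel",
]

PANEL_COLUMNS = ("city", "date", "pollutant", "value")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format panel contract and return a normalized copy.

    Requires columns (city, date, pollutant, value), unique keys, and a
    contiguous daily date range within every (city, pollutant) series.
    """
    missing_cols = set(PANEL_COLUMNS) - set(panel.columns)
    if missing_cols:
        raise ValueError(f"panel missing columns: {sorted(missing_cols)}")
    out = panel.loc[:, list(PANEL_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"])
    if out.duplicated(["city", "date", "pollutant"]).any():
        raise ValueError("duplicate (city, date, pollutant) keys in panel")
    out = out.sort_values(["pollutant", "city", "date"], ignore_index=True)
    for (pol, city), grp in out.groupby(["pollutant", "city"], sort=False):
        d = grp["date"]
        step = d.diff().dropna()
        if len(step) and not (step == pd.Timedelta(days=1)).all():
            raise ValueError(
                f"series ({city}, {pol}) is not a contiguous daily sequence"
            )
    return out


def _series_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """Wide frame: rows = date, columns = (pollutant, city)."""
    return panel.pivot(index="date", columns=["pollutant", "city"], values="value")


def impute_missing(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with the mean of the nearest neighbours.

    Each missing value in a (city, pollutant) series is replaced by the
    average of the closest non-missing observation before the gap and
    the closest one after it; runs of consecutive missing days therefore
    all receive the same fill.  Original values are never altered, and
    applying the operation twice equals applying it once.

    Raises
    ------
    ValueError
        If a series is entirely missing or is missing an endpoint (no
        valid neighbour on one side), naming the series and date.
    """
    panel = validate_panel(panel)
    if panel["value"].notna().all():
        return panel
    wide = _series_frame(panel)
    for col in wide.columns[wide.isna().all(axis=0)]:
        raise ValueError(f"series (city={col[1]}, pollutant={col[0]}) is entirely missing")
    head_bad = wide.isna().iloc[0]
    tail_bad = wide.isna().iloc[-1]
    for col in wide.columns[head_bad | tail_bad]:
        when = wide.index[0] if head_bad[col] else wide.index[-1]
        raise ValueError(
            f"series (city={col[1]}, pollutant={col[0]}) missing endpoint at "
            f"{when.date()}: no neighbour on one side"
        )
    filled = (wide.ffill() + wide.bfill()) / 2.0
    long = (
        filled.stack(["pollutant", "city"], future_stack=True)
        .rename("value")
        .reset_index()
        .sort_values(["pollutant", "city", "date"], ignore_index=True)
    )
    return long[["city", "date", "pollutant", "value"]]


def half_year_means(panel: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    """Per-city means over calendar half-years (Jan-Jun, Jul-Dec).

    Returns a tidy table (city, half, mean, n_days, partial) where
    ``half`` is e.g. ``"2015H1"`` and ``partial`` flags halves whose
    observed day count falls short of the full calendar half (those
    means average only the available days).
    """
    panel = validate_panel(panel)
    sub = panel[panel["pollutant"] == pollutant]
    if sub.empty:
        raise ValueError(f"unknown pollutant label: {pollutant!r}")
    sub = sub.copy()
    half_no = (sub["date"].dt.month > 6).astype(int) + 1
    sub["half"] = sub["date"].dt.year.astype(str) + "H" + half_no.astype(str)
    out = (
        sub.groupby(["city", "half"])
        .agg(mean=("value", "mean"), n_days=("value", "size"))
        .reset_index()
    )

    def _full_days(half: str) -> int:
        year, h = int(half[:4]), half[-1]
        start, end = (f"{year}-01-01", f"{year}-06-30") if h == "1" else (
            f"{year}-07-01", f"{year}-12-31")
        return len(pd.date_range(start, end, freq="D"))

    out["partial"] = out.apply(lambda r: r["n_days"] < _full_days(r["half"]), axis=1)
    return out.sort_values(["city", "half"], ignore_index=True)


@dataclass
class StationaryPanel:
    """Stationarity-screened series plus the differencing ledger.

    ``series`` maps (city, pollutant) to the level series *after
    imputation*; ``n_diffs`` records how many first differences each
    series needed to pass the ADF test.  ``get`` materialises a series
    at any differencing order >= its own, which lets a city pair be
    aligned at the max of the two orders so the pairwise VAR is
    balanced.
    """

    series: dict[tuple[str, str], np.ndarray]
    n_diffs: dict[tuple[str, str], int]
    ledger: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    def cities(self, pollutant: str) -> list[str]:
        return sorted({c for (c, p) in self.series if p == pollutant})

    def pollutants(self) -> list[str]:
        return sorted({p for (_, p) in self.series})

    def get(self, city: str, pollutant: str, order: int | None = None) -> np.ndarray:
        base = self.series[(city, pollutant)]
        d = self.n_diffs[(city, pollutant)] if order is None else order
        if d < self.n_diffs[(city, pollutant)]:
            raise ValueError("cannot return a series below its stationary order")
        return np.diff(base, n=d) if d else base.copy()

    def aligned_pair(
        self, city_x: str, city_y: str, pollutant: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Both cities' series at the max of their differencing orders."""
        d = max(self.n_diffs[(city_x, pollutant)], self.n_diffs[(city_y, pollutant)])
        return self.get(city_x, pollutant, d), self.get(city_y, pollutant, d)


def _adf_maxlag(t: int) -> int:
    # Schwert-style cap on the ADF lag order searched by AIC
    return int(np.floor(12.0 * (t / 100.0) ** 0.25))


def ensure_stationary(
    panel: pd.DataFrame,
    alpha: float = 0.05,
    max_diffs: int = 2,
) -> StationaryPanel:
    """ADF-screen every series, differencing until stationary.

    Each (city, pollutant) series is tested with an ADF regression
    including a constant (no trend), lag order chosen by AIC up to
    ``12 * (T/100)**0.25``.  While the p-value is >= ``alpha`` and fewer
    than ``max_diffs`` differences have been taken, the series is
    first-differenced and retested.  Every test performed is recorded in
    the ledger (city, pollutant, diff_order, adf_statistic, adf_pvalue,
    passed).

    Raises
    ------
    ValueError
        If alpha or max_diffs are out of range, the panel still has
        missing values, or some series remain non-stationary after
        ``max_diffs`` differences (all offenders listed).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if max_diffs < 1:
        raise ValueError("max_diffs must be >= 1")
    panel = validate_panel(panel)
    if panel["value"].isna().any():
        raise ValueError("panel contains missing values; run impute_missing first")

    series: dict[tuple[str, str], np.ndarray] = {}
    n_diffs: dict[tuple[str, str], int] = {}
    rows = []
    failures = []
    for (pol, city), grp in panel.groupby(["pollutant", "city"], sort=True):
        level = grp.sort_values("date")["value"].to_numpy(float)
        x, d = level, 0
        while True:
            stat, pval, *_ = adfuller(
                x, maxlag=_adf_maxlag(len(x)), regression="c", autolag="AIC"
            )
            rows.append(
                {"city": city, "pollutant": pol, "diff_order": d,
                 "adf_statistic": stat, "adf_pvalue": pval, "passed": pval < alpha}
            )
            if pval < alpha:
                break
            if d >= max_diffs:
                failures.append((city, pol))
                break
            x, d = np.diff(x), d + 1
        series[(city, pol)] = level
        n_diffs[(city, pol)] = d
    if failures:
        names = ", ".join(f"({c}, {p})" for c, p in failures)
        raise ValueError(
            f"series non-stationary after {max_diffs} differences: {names}"
        )
    ledger = pd.DataFrame(rows)
    return StationaryPanel(series=series, n_diffs=n_diffs, ledger=ledger, alpha=alpha)
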