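import numpy as np
import pandas as pd
import pytest

from aqnet.preprocess import (
    ensure_stationary,
    half_year_means,
    impute_missing,
    validate_panel,
)

from conftest import series_panel


class TestImputeMissing:
    def test_single_gap_filled_with_midpoint(self):
        panel = series_panel({"a": [10.0, np.nan, 14.0]})
        out = impute_missing(panel)
        assert out["value"].tolist() == [10.0, 12.0, 14.0]

    def test_run_of_gaps_shares_neighbours(self):
        panel = series_panel({"a": [10.0, np.nan, np.nan, 22.0]})
        out = impute_missing(panel)
        assert out["value"].tolist() == [10.0, 16.0, 16.0, 22.0]

    def test_complete_panel_returned_unchanged(self):
        panel = series_panel({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = impute_missing(panel)
        pd.testing.assert_frame_equal(out, validate_panel(panel))

    def test_idempotent(self, small_panel):
        panel, _ = small_panel
        once = impute_missing(panel)
        twice = impute_missing(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_observed_values_never_altered(self, small_panel):
        panel, _ = small_panel
        out = impute_missing(panel)
        obs = validate_panel(panel)
        mask = obs["value"].notna()
        assert np.allclose(out.loc[mask, "value"], obs.loc[mask, "value"])

    def test_missing_endpoint_is_an_error_naming_the_series(self):
        panel = series_panel({"a": [np.nan, 2.0, 3.0]})
        with pytest.raises(ValueError, match="city=a.*2015-01-06"):
            impute_missing(panel)

    def test_entirely_missing_series_is_an_error(self):
        panel = series_panel({"a": [np.nan, np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(panel)


class TestValidatePanel:
    def test_duplicate_keys_rejected(self):
        panel = series_panel({"a": [1.0, 2.0]})
        dup = pd.concat([panel, panel.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            validate_panel(dup)

    def test_gap_in_dates_rejected(self):
        panel = series_panel({"a": [1.0, 2.0, 3.0]})
        panel.loc[2, "date"] = pd.Timestamp("2015-01-20")
        with pytest.raises(ValueError, match="contiguous"):
            validate_panel(panel)


class TestHalfYearMeans:
    def test_constant_series_gives_constant_means(self):
        panel = series_panel({"a": [7.0] * 365}, start="2015-01-01")
        out = half_year_means(panel, "AQI")
        assert np.allclose(out["mean"], 7.0)
        assert set(out["half"]) == {"2015H1", "2015H2"}

    def test_piecewise_constant_year_splits_at_july(self):
        values = [1.0] * 181 + [3.0] * 184  # Jan-Jun then Jul-Dec of 2015
        panel = series_panel({"a": values}, start="2015-01-01")
        out = half_year_means(panel, "AQI").set_index("half")
        assert out.loc["2015H1", "mean"] == 1.0
        assert out.loc["2015H2", "mean"] == 3.0
        assert not out["partial"].any()

    def test_partial_half_flagged(self):
        panel = series_panel({"a": [5.0] * 40}, start="2015-01-06")
        out = half_year_means(panel, "AQI")
        assert out["partial"].all()

    def test_winter_peaked_city_has_higher_first_half(self):
        days = pd.date_range("2015-01-01", "2015-12-31", freq="D")
        vals = 50 + 20 * np.cos(2 * np.pi * (days.dayofyear - 15) / 365.25)
        panel = series_panel({"a": list(vals)}, start="2015-01-01")
        out = half_year_means(panel, "AQI").set_index("half")
        assert out.loc["2015H1", "mean"] > out.loc["2015H2", "mean"]

    def test_unknown_pollutant_rejected(self):
        panel = series_panel({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unknown pollutant"):
            half_year_means(panel, "PM2.5")


def _ar1(phi, t, seed, scale=1.0):
    g = np.random.default_rng(seed)
    e = g.normal(size=t, scale=scale)
    x = np.empty(t)
    x[0] = e[0]
    for i in range(1, t):
        x[i] = phi * x[i - 1] + e[i]
    return x


class TestEnsureStationary:
    @pytest.mark.parametrize(
        "kind,expected_diffs",
        [("white_noise", 0), ("ar_half", 0), ("random_walk", 1)],
    )
    def test_adf_screen_classifies_canonical_series(self, kind, expected_diffs):
        """White noise and stationary AR(1) pass at level; a pure random
        walk needs exactly one difference, in nearly all seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            g = np.random.default_rng(1000 + seed)
            if kind == "white_noise":
                x = g.normal(size=879)
            elif kind == "ar_half":
                x = _ar1(0.5, 879, 1000 + seed)
            else:
                x = np.cumsum(g.normal(size=879))
            panel = series_panel({"a": list(x), "b": list(g.normal(size=879))})
            stat = ensure_stationary(panel, alpha=0.05, max_diffs=2)
            hits += stat.n_diffs[("a", "AQI")] == expected_diffs
        assert hits >= int(0.9 * n_seeds)

    def test_ledger_consistent_with_series_lengths(self):
        g = np.random.default_rng(0)
        walk = np.cumsum(g.normal(size=500))
        panel = series_panel({"a": list(walk), "b": list(g.normal(size=500))})
        stat = ensure_stationary(panel)
        for (city, pol), d in stat.n_diffs.items():
            assert len(stat.get(city, pol)) == 500 - d
            tests = stat.ledger.query("city == @city and pollutant == @pol")
            assert tests["diff_order"].max() == d
            assert tests["passed"].iloc[-1]

    def test_affine_rescaling_does_not_change_decisions(self):
        g = np.random.default_rng(5)
        x = _ar1(0.6, 600, 5)
        a = ensure_stationary(series_panel({"a": list(x), "b": list(g.normal(size=600))}))
        b = ensure_stationary(
            series_panel({"a": list(100.0 + 7.0 * x), "b": list(g.normal(size=600))})
        )
        assert a.n_diffs[("a", "AQI")] == b.n_diffs[("a", "AQI")]

    def test_stubborn_series_raises_listing_offenders(self):
        t = np.arange(400, dtype=float)
        g = np.random.default_rng(2)
        # quadratic trend stays non-stationary through 1 difference
        panel = series_panel(
            {"bad": list(0.01 * t**2 + g.normal(size=400, scale=0.01)),
             "ok": list(g.normal(size=400))}
        )
        with pytest.raises(ValueError, match="bad"):
            ensure_stationary(panel, alpha=0.05, max_diffs=1)

    def test_missing_values_rejected(self):
        panel = series_panel({"a": [1.0, np.nan, 3.0] + [0.0] * 60})
        with pytest.raises(ValueError, match="missing"):
            ensure_stationary(panel)

    def test_aligned_pair_uses_max_difference_order(self):
        g = np.random.default_rng(3)
        walk = np.cumsum(g.normal(size=600))
        flat = g.normal(size=600)
        stat = ensure_stationary(series_panel({"w": list(walk), "f": list(flat)}))
        assert stat.n_diffs[("w", "AQI")] == 1
        assert stat.n_diffs[("f", "AQI")] == 0
        xs, ys = stat.aligned_pair("w", "f", "AQI")
        assert len(xs) == len(ys) == 599
        # the level series is returned differenced to match its partner
        assert np.allclose(ys, np.diff(flat))

    def test_below_stationary_order_refused(self):
        g = np.random.default_rng(3)
        walk = np.cumsum(g.normal(size=600))
        stat = ensure_stationary(series_panel({"w": list(walk),
                                               "f": list(g.normal(size=600))}))
        with pytest.raises(ValueError, match="below its stationary order"):
            stat.get("w", "AQI", 0)
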