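"""Rolling-window covariate engineering, thresholds, daylength, catalog."""

import numpy as np
import pandas as pd
import pytest

import locustgam as lg
from locustgam.covariates import (
    LONG_WINDOW,
    SHORT_WINDOW,
    ThresholdSpec,
    WindowSpec,
    apply_scaling,
    build_feature_table,
    daylength,
    default_catalog,
    engineer_grid,
    engineer_rows,
    extract_at_site,
    standardize,
    threshold_counts,
    window_stat,
)


def _daily_series(start, values):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx)


class TestWindowStat:
    def test_worked_example_mid_march(self):
        """Short-window mean rain for a 15 March survey averages the daily
        rain from 5 March through 15 March (11 inclusive values)."""
        rng = np.random.default_rng(0)
        vals = rng.exponential(2.0, 80)
        s = _daily_series("2010-01-01", vals)
        got = window_stat(s, "2010-03-15", SHORT_WINDOW, "mean")
        expected = s.loc["2010-03-05":"2010-03-15"].mean()
        assert got == pytest.approx(expected, abs=1e-12)
        assert len(s.loc["2010-03-05":"2010-03-15"]) == 11

    def test_constant_series_returns_constant(self):
        s = _daily_series("2010-01-01", np.full(100, 3.7))
        for w in (SHORT_WINDOW, LONG_WINDOW):
            for stat in ("min", "max", "mean"):
                assert window_stat(s, "2010-03-20", w, stat) == pytest.approx(3.7)

    def test_long_window_max_equals_bruteforce(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=61)
        s = _daily_series("2010-01-01", vals)
        got = window_stat(s, "2010-03-02", LONG_WINDOW, "max")
        assert got == max(vals)  # exhaustive scan over all 61 values

    def test_one_day_shift_moves_window_one_day(self):
        rng = np.random.default_rng(2)
        s = _daily_series("2010-01-01", rng.normal(size=100))
        m1 = window_stat(s, "2010-03-10", SHORT_WINDOW, "mean")
        m2 = window_stat(s, "2010-03-11", SHORT_WINDOW, "mean")
        # drop the oldest value, add the newest
        delta = (s.loc["2010-03-11"] - s.loc["2010-02-28"]) / 11
        assert m2 - m1 == pytest.approx(delta, abs=1e-12)

    def test_insufficient_history_raises(self):
        s = _daily_series("2010-03-10", np.ones(30))
        with pytest.raises(ValueError, match="insufficient"):
            window_stat(s, "2010-03-15", SHORT_WINDOW, "mean")


class TestThresholdCounts:
    def test_all_dry_short_window_counts_eleven(self):
        rain = _daily_series("2010-01-01", np.zeros(60))
        tmin = _daily_series("2010-01-01", np.full(60, 20.0))
        tmax = _daily_series("2010-01-01", np.full(60, 30.0))
        dry, below, above = threshold_counts(tmin, tmax, rain, "2010-02-15",
                                             SHORT_WINDOW)
        assert (dry, below, above) == (11, 0, 0)

    def test_three_hot_days_counted(self):
        vals = np.full(80, 30.0)
        vals[40:43] = 43.0
        tmax = _daily_series("2010-01-01", vals)
        tmin = _daily_series("2010-01-01", np.full(80, 20.0))
        rain = _daily_series("2010-01-01", np.ones(80))
        dry, below, above = threshold_counts(tmin, tmax, rain, "2010-03-20",
                                             LONG_WINDOW)
        assert above == 3 and dry == 0

    def test_counts_match_bruteforce_loops(self):
        rng = np.random.default_rng(3)
        n = 120
        tmin = _daily_series("2010-01-01", rng.uniform(5, 25, n))
        tmax = _daily_series("2010-01-01", rng.uniform(25, 45, n))
        rain = _daily_series("2010-01-01",
                             rng.exponential(1.0, n) * (rng.uniform(size=n) > 0.6))
        date = pd.Timestamp("2010-03-20")
        for w in (SHORT_WINDOW, LONG_WINDOW):
            got = threshold_counts(tmin, tmax, rain, date, w)
            days = pd.date_range(date - pd.Timedelta(days=w.length), date)
            brute = (
                sum(rain.loc[d] <= 0.0 for d in days),
                sum(tmin.loc[d] < 18.0 for d in days),
                sum(tmax.loc[d] > 42.0 for d in days),
            )
            assert got == brute


class TestExtractAtSite:
    def test_cell_center_returns_cell_values(self, env):
        iy, ix = 5, 7
        vals = extract_at_site(env, env.lons[ix], env.lats[iy], env.dates[40])
        assert vals["tmax"] == env.tmax[iy, ix, 40]
        assert vals["clay"] == env.clay[iy, ix]

    def test_nearest_neighbour_crosses_midpoint(self, env):
        # 0.026 deg east of a centre with 0.05 spacing snaps to the next cell
        lon = env.lons[3] + 0.026
        vals = extract_at_site(env, lon, env.lats[2], env.dates[40])
        assert vals["tmax"] == env.tmax[2, 4, 40]

    def test_random_sites_match_exhaustive_search(self, env):
        rng = np.random.default_rng(4)
        for _ in range(100):
            lon = rng.uniform(env.lons[0], env.lons[-1])
            lat = rng.uniform(env.lats[0], env.lats[-1])
            iy, ix = env.nearest_cell(lon, lat)
            d2 = (env.lons[None, :] - lon) ** 2 + (env.lats[:, None] - lat) ** 2
            jy, jx = np.unravel_index(np.argmin(d2), d2.shape)
            assert d2[iy, ix] == pytest.approx(d2[jy, jx], abs=1e-15)

    def test_outside_grid_raises(self, env):
        with pytest.raises(ValueError, match="outside"):
            extract_at_site(env, env.lons[-1] + 1.0, env.lats[0], env.dates[40])


class TestDaylength:
    def test_equator_near_twelve_hours(self):
        for doy in (1, 90, 180, 270, 355):
            assert daylength(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_matches_noaa_equation(self):
        """Independent oracle: NOAA's Fourier-series solar declination in the
        sunrise equation, agreement within 0.1 h."""

        def noaa_daylength(lat, doy):
            g = 2 * np.pi / 365 * (doy - 1)
            decl = (
                0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
                - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
                - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
            )
            cos_h = -np.tan(np.deg2rad(lat)) * np.tan(decl)
            return 24 / np.pi * np.arccos(np.clip(cos_h, -1, 1))

        for lat, doy in [(-35.0, 355), (-35.0, 172), (-25.0, 80), (40.0, 200)]:
            assert daylength(lat, doy) == pytest.approx(
                noaa_daylength(lat, doy), abs=0.1
            )

    def test_hemispheric_symmetry(self):
        for lat, doy in [(-35, 10), (20, 100), (-50, 200)]:
            assert daylength(lat, doy) + daylength(-lat, doy) == pytest.approx(
                24.0, abs=0.3
            )

    def test_polar_latitudes_rejected(self):
        with pytest.raises(ValueError):
            daylength(-70.0, 100)


class TestCatalog:
    def test_candidate_arithmetic(self):
        cat = default_catalog()
        # 5 vars x 2 windows x 3 stats - 2 rain minima + 6 counts + 5 extras
        assert len(cat.candidates) == 39
        assert "rain_min_10d" not in cat.candidates
        assert "rain_min_60d" not in cat.candidates

    def test_full_and_reduced_sizes(self):
        cat = default_catalog()
        assert len(cat.excluded) == 12
        assert len(cat.full) == 27
        assert len(cat.reduced) == 10
        assert set(cat.reduced) <= set(cat.full) <= set(cat.candidates)

    def test_reduced_is_the_interpretation_set(self):
        assert set(default_catalog().reduced) == {
            "rain_mean_60d", "tmax_mean_60d", "days_above42_60d", "vp_mean_60d",
            "vp_max_60d", "vp_mean_10d", "rad_mean_10d", "daylength_h",
            "ndvi", "sand",
        }


class TestFeatureTable:
    def test_negative_ndvi_rows_dropped_and_counted(self, env, surveys):
        import dataclasses

        sub = surveys.head(100).copy().reset_index(drop=True)
        env2 = dataclasses.replace(env, ndvi=env.ndvi.copy())
        # force the NDVI seen by exactly the first two surveys negative
        for i in range(2):
            iy, ix = env2.nearest_cell(sub.loc[i, "lon"], sub.loc[i, "lat"])
            m = env2.month_index(sub.loc[i, "date"])
            env2.ndvi[iy, ix, m] = -0.05
        # brute-force oracle: count surveys whose nearest cell-month NDVI < 0
        expected = 0
        for _, r in sub.iterrows():
            iy, ix = env2.nearest_cell(r["lon"], r["lat"])
            m = env2.month_index(r["date"])
            if env2.ndvi[iy, ix, m] < 0:
                expected += 1
        tbl = build_feature_table(sub, env2)
        assert expected >= 2  # the two injected negatives are seen
        assert tbl.attrs["dropped_ndvi"] == expected
        assert len(tbl) == 100 - expected - tbl.attrs["dropped_history"]
        assert (tbl["ndvi"] >= 0).all()

    def test_insufficient_history_rows_dropped(self, env, surveys):
        sub = surveys.head(50).copy()
        sub.loc[sub.index[:3], "date"] = env.dates[10]  # < 60 days of history
        tbl = build_feature_table(sub, env)
        assert tbl.attrs["dropped_history"] == 3
        assert tbl.attrs["dropped_history"] + tbl.attrs["dropped_ndvi"] + len(tbl) == 50

    def test_candidate_columns_present_and_complete(self, table):
        cat = default_catalog()
        assert all(c in table.columns for c in cat.candidates)
        assert len(cat.candidates) == 39
        assert not table[list(cat.candidates)].isna().any().any()
        assert table["response"].min() >= 0
        assert table["doy"].between(1, 366).all()

    def test_engineered_rows_match_elementary_ops(self, env, surveys):
        """Bulk engineering equals the one-survey operations row by row."""
        sub = surveys.head(40)
        tbl = engineer_rows(env, sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                            sub["date"])
        for i, row in sub.reset_index(drop=True).iterrows():
            iy, ix = env.nearest_cell(row["lon"], row["lat"])
            for var in ("rain", "tmax", "vp"):
                series = pd.Series(getattr(env, var)[iy, ix, :], index=env.dates)
                for w in (SHORT_WINDOW, LONG_WINDOW):
                    for stat in ("min", "max", "mean"):
                        key = f"{var}_{stat}_{w.length}d"
                        if key not in tbl.columns:
                            continue
                        assert tbl.loc[i, key] == pytest.approx(
                            window_stat(series, row["date"], w, stat), abs=1e-12
                        )
            tmin_s = pd.Series(env.tmin[iy, ix, :], index=env.dates)
            tmax_s = pd.Series(env.tmax[iy, ix, :], index=env.dates)
            rain_s = pd.Series(env.rain[iy, ix, :], index=env.dates)
            for w in (SHORT_WINDOW, LONG_WINDOW):
                dry, below, above = threshold_counts(
                    tmin_s, tmax_s, rain_s, row["date"], w
                )
                assert tbl.loc[i, f"dry_days_{w.length}d"] == dry
                assert tbl.loc[i, f"days_below18_{w.length}d"] == below
                assert tbl.loc[i, f"days_above42_{w.length}d"] == above

    def test_grid_row_reproduces_survey_row_at_cell_center(self, env):
        date = env.dates[100]
        iy, ix = 4, 9
        grid_tbl = engineer_grid(env, date)
        row_tbl = engineer_rows(env, [env.lons[ix]], [env.lats[iy]], [date])
        cell = grid_tbl.iloc[iy * len(env.lons) + ix]
        for col in default_catalog().candidates:
            assert cell[col] == pytest.approx(row_tbl.loc[0, col], abs=1e-12)

    def test_grid_requires_history(self, env):
        with pytest.raises(ValueError, match="history"):
            engineer_grid(env, env.dates[10])


class TestStandardize:
    def test_training_columns_centred_and_scaled(self, table):
        cols = list(default_catalog().full)
        mask = np.zeros(len(table), dtype=bool)
        mask[: len(table) // 2] = True
        std, rec = standardize(table, cols, mask)
        tr = std.loc[mask, cols]
        assert np.allclose(tr.mean(), 0.0, atol=1e-12)
        assert np.allclose(tr.std(ddof=1), 1.0, atol=1e-12)

    def test_double_application_refused(self, table):
        cols = ["ndvi", "sand"]
        std, rec = standardize(table, cols)
        with pytest.raises(ValueError, match="already standardized"):
            apply_scaling(std, rec)
        with pytest.raises(ValueError, match="already standardized"):
            standardize(std, cols)

    def test_validation_rows_not_centred_in_general(self, table):
        cols = ["vp_mean_60d"]
        mask = np.zeros(len(table), dtype=bool)
        mask[: len(table) // 2] = True
        std, rec = standardize(table, cols, mask)
        val_mean = std.loc[~mask, cols[0]].mean()
        # recompute with held-out statistics: training stats differ from
        # validation stats, so the scaled validation mean is nonzero
        held = table.loc[~mask, cols[0]]
        expected = (held.mean() - rec.means[0]) / rec.sds[0]
        assert val_mean == pytest.approx(expected, abs=1e-12)
        assert abs(val_mean) > 1e-6

    def test_zero_variance_column_named(self, table):
        t = table.copy()
        t["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            standardize(t, ["ndvi", "flat"])
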