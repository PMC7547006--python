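"""Per-survey covariate engineering.

Each survey is paired with rolling-window summaries of daily weather over a
short (10-day) and a long (60-day) memory window ending on the survey date,
counts of threshold days (dry days, minima below 18 degC, maxima above
42 degC), the monthly NDVI at the nearest cell, static soil fractions, and
the astronomical daylength.  Windows are inclusive of the survey date, so a
"10 day" window covers 11 daily values, and advancing the survey date by one
day shifts the window by one day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .density import TransformConfig, power_transform
from .grids import EnvGrid

__all__ = [
    "WindowSpec",
    "ThresholdSpec",
    "CovariateCatalog",
    "ScalingRecord",
    "SHORT_WINDOW",
    "LONG_WINDOW",
    "default_catalog",
    "window_stat",
    "threshold_counts",
    "extract_at_site",
    "daylength",
    "engineer_rows",
    "engineer_grid",
    "build_feature_table",
    "standardize",
    "apply_scaling",
]

_WEATHER_VARS = ("tmax", "tmin", "rain", "vp", "rad")
_STATS = ("min", "max", "mean")


@dataclass(frozen=True)
class WindowSpec:
    """A memory window of `length` days ending on (and including) the survey
    date, i.e. covering length + 1 daily values."""

    name: str
    length: int
    statistics: tuple[str, ...] = _STATS

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("window length must be >= 1 day")


SHORT_WINDOW = WindowSpec("short", 10)
LONG_WINDOW = WindowSpec("long", 60)


@dataclass(frozen=True)
class ThresholdSpec:
    """Thresholds for counting ecologically limiting days.

    A dry day has rain <= dry_rain_threshold (mm); cold/hot days have a daily
    minimum below 18 degC or a maximum above 42 degC respectively.
    """

    dry_rain_threshold: float = 0.0
    cold_tmin_threshold: float = 18.0
    hot_tmax_threshold: float = 42.0


@dataclass(frozen=True)
class CovariateCatalog:
    """Named covariate sets: all candidates, the exclusion list, the resulting
    full-model set, and the reduced interpretation set."""

    candidates: tuple[str, ...]
    excluded: tuple[str, ...]
    reduced: tuple[str, ...]

    def __post_init__(self) -> None:
        cand, excl, red = set(self.candidates), set(self.excluded), set(self.reduced)
        if not excl <= cand:
            raise ValueError("excluded names must be candidates")
        full = cand - excl
        if not red <= full:
            raise ValueError("reduced set must be a subset of the full set")

    @property
    def full(self) -> tuple[str, ...]:
        excl = set(self.excluded)
        return tuple(c for c in self.candidates if c not in excl)


def default_catalog() -> CovariateCatalog:
    """The default catalogue: 39 candidates, 12 exclusions -> 27 full-model
    covariates, and the 10-covariate reduced set.

    Candidate arithmetic: 5 weather variables x 2 windows x 3 statistics,
    minus the two rain minima (uninformative: almost always 0), plus 6
    threshold-day counts, NDVI, daylength and 3 soil fractions.
    """
    candidates = []
    for var in _WEATHER_VARS:
        for wl in (10, 60):
            for stat in _STATS:
                if var == "rain" and stat == "min":
                    continue  # long-run rain minima are ~always 0 mm/day
                candidates.append(f"{var}_{stat}_{wl}d")
    for wl in (10, 60):
        candidates += [f"dry_days_{wl}d", f"days_below18_{wl}d", f"days_above42_{wl}d"]
    candidates += ["ndvi", "daylength_h", "clay", "sand", "silt"]

    excluded = (
        "tmin_min_10d", "tmin_max_10d", "tmin_mean_10d",
        "tmin_min_60d", "tmin_max_60d", "tmin_mean_60d",
        "rain_max_10d", "rain_max_60d",
        "tmax_min_10d", "tmax_max_10d",
        "dry_days_10d", "dry_days_60d",
    )
    reduced = (
        "rain_mean_60d", "tmax_mean_60d", "days_above42_60d",
        "vp_mean_60d", "vp_max_60d", "vp_mean_10d",
        "rad_mean_10d", "daylength_h", "ndvi", "sand",
    )
    return CovariateCatalog(tuple(candidates), excluded, reduced)


# ---------------------------------------------------------------------------
# elementary operations


def window_stat(
    series: pd.Series, survey_date, window: WindowSpec, stat: str
) -> float:
    """Statistic of a daily series over the inclusive window ending on
    survey_date.  The series must be indexed by date and cover the window."""
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {_STATS}")
    end = pd.Timestamp(survey_date)
    start = end - pd.Timedelta(days=window.length)
    vals = series.loc[start:end]
    if len(vals) != window.length + 1:
        raise ValueError(
            f"insufficient history: window {start.date()}..{end.date()} has "
            f"{len(vals)} of {window.length + 1} daily values"
        )
    return float(getattr(np, stat)(vals.to_numpy()))


def threshold_counts(
    tmin: pd.Series,
    tmax: pd.Series,
    rain: pd.Series,
    survey_date,
    window: WindowSpec,
    spec: ThresholdSpec = ThresholdSpec(),
) -> tuple[int, int, int]:
    """Counts of (dry days, days with tmin < 18, days with tmax > 42) in the
    inclusive window ending on survey_date."""
    end = pd.Timestamp(survey_date)
    start = end - pd.Timedelta(days=window.length)
    out = []
    for series, fn in (
        (rain, lambda v: v <= spec.dry_rain_threshold),
        (tmin, lambda v: v < spec.cold_tmin_threshold),
        (tmax, lambda v: v > spec.hot_tmax_threshold),
    ):
        vals = series.loc[start:end].to_numpy()
        if len(vals) != window.length + 1:
            raise ValueError("insufficient history for threshold counts")
        out.append(int(np.sum(fn(vals))))
    return tuple(out)


def extract_at_site(env: EnvGrid, lon: float, lat: float, date) -> dict[str, float]:
    """Values of every gridded variable at the cell nearest the site on the
    given date (NDVI from the calendar month containing the date)."""
    iy, ix = env.nearest_cell(lon, lat)
    t = env.date_index(date)
    m = env.month_index(date)
    out = {name: float(getattr(env, name)[iy, ix, t]) for name in _WEATHER_VARS}
    out["ndvi"] = float(env.ndvi[iy, ix, m])
    for name in ("clay", "sand", "silt"):
        out[name] = float(getattr(env, name)[iy, ix])
    return out


def daylength(lat: float, doy: int) -> float:
    """Astronomical daylength (hours) from the standard solar declination and
    hour-angle formulae; valid away from the polar circles."""
    if abs(lat) >= 66.5:
        raise ValueError(f"latitude {lat} outside the supported range (|lat| < 66.5)")
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.0))
    cos_h = -np.tan(np.deg2rad(lat)) * np.tan(decl)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return float(24.0 / np.pi * np.arccos(cos_h))


def _daylength_vec(lat: np.ndarray, doy: np.ndarray) -> np.ndarray:
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.0))
    cos_h = np.clip(-np.tan(np.deg2rad(lat)) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h)


# ---------------------------------------------------------------------------
# bulk engineering


def _stat_reduce(a: np.ndarray, stat: str, axis: int = -1) -> np.ndarray:
    return getattr(np, stat)(a, axis=axis)


def engineer_rows(
    env: EnvGrid,
    lons: np.ndarray,
    lats: np.ndarray,
    dates,
    thresholds: ThresholdSpec = ThresholdSpec(),
    windows: tuple[WindowSpec, WindowSpec] = (SHORT_WINDOW, LONG_WINDOW),
) -> pd.DataFrame:
    """Compute every candidate covariate for arbitrary (lon, lat, date) rows.

    Rows whose long window extends before the grid calendar are flagged in the
    boolean column ``insufficient_history`` (their covariates are NaN) rather
    than dropped, so callers control the bookkeeping.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    dates = pd.DatetimeIndex(dates)
    n = len(lons)
    cells = [env.nearest_cell(lo, la) for lo, la in zip(lons, lats)]
    tidx = env.dates.get_indexer(dates.normalize())
    if np.any(tidx < 0):
        raise ValueError("some survey dates are outside the grid calendar")
    longest = max(w.length for w in windows)
    insufficient = tidx < longest

    cols: dict[str, np.ndarray] = {}
    cand = default_catalog().candidates
    for name in cand:
        cols[name] = np.full(n, np.nan)

    daily = {name: getattr(env, name) for name in _WEATHER_VARS}
    for i in range(n):
        if insufficient[i]:
            continue
        iy, ix = cells[i]
        t = tidx[i]
        for w in windows:
            sl = slice(t - w.length, t + 1)
            for var in _WEATHER_VARS:
                seg = daily[var][iy, ix, sl]
                for stat in _STATS:
                    key = f"{var}_{stat}_{w.length}d"
                    if key in cols:
                        cols[key][i] = _stat_reduce(seg, stat)
            rain_seg = daily["rain"][iy, ix, sl]
            tmin_seg = daily["tmin"][iy, ix, sl]
            tmax_seg = daily["tmax"][iy, ix, sl]
            cols[f"dry_days_{w.length}d"][i] = np.sum(
                rain_seg <= thresholds.dry_rain_threshold
            )
            cols[f"days_below18_{w.length}d"][i] = np.sum(
                tmin_seg < thresholds.cold_tmin_threshold
            )
            cols[f"days_above42_{w.length}d"][i] = np.sum(
                tmax_seg > thresholds.hot_tmax_threshold
            )
        m = env.month_index(dates[i])
        cols["ndvi"][i] = env.ndvi[iy, ix, m]
        for s in ("clay", "sand", "silt"):
            cols[s][i] = getattr(env, s)[iy, ix]

    doy = dates.dayofyear.to_numpy().astype(float)
    cols["daylength_h"] = np.where(
        insufficient, np.nan, _daylength_vec(lats, doy)
    )
    out = pd.DataFrame(cols)
    out["lon"] = lons
    out["lat"] = lats
    out["doy"] = doy
    out["date"] = dates
    out["insufficient_history"] = insufficient
    return out


def engineer_grid(
    env: EnvGrid,
    date,
    thresholds: ThresholdSpec = ThresholdSpec(),
    windows: tuple[WindowSpec, WindowSpec] = (SHORT_WINDOW, LONG_WINDOW),
) -> pd.DataFrame:
    """Candidate covariates for every grid cell on one date (vectorised).

    A cell containing a survey site yields exactly the survey's covariate row
    for the same date, because both paths apply the same reductions to the
    same cell series.
    """
    t = env.date_index(date)
    longest = max(w.length for w in windows)
    if t < longest:
        raise ValueError(
            f"grid calendar provides only {t} days of history before {date}; "
            f"{longest} required"
        )
    ny, nx = len(env.lats), len(env.lons)
    cols: dict[str, np.ndarray] = {}
    for w in windows:
        sl = slice(t - w.length, t + 1)
        for var in _WEATHER_VARS:
            seg = getattr(env, var)[:, :, sl]
            for stat in _STATS:
                key = f"{var}_{stat}_{w.length}d"
                cols[key] = _stat_reduce(seg, stat).ravel()
        rain_seg = env.rain[:, :, sl]
        tmin_seg = env.tmin[:, :, sl]
        tmax_seg = env.tmax[:, :, sl]
        cols[f"dry_days_{w.length}d"] = np.sum(
            rain_seg <= thresholds.dry_rain_threshold, axis=-1
        ).ravel().astype(float)
        cols[f"days_below18_{w.length}d"] = np.sum(
            tmin_seg < thresholds.cold_tmin_threshold, axis=-1
        ).ravel().astype(float)
        cols[f"days_above42_{w.length}d"] = np.sum(
            tmax_seg > thresholds.hot_tmax_threshold, axis=-1
        ).ravel().astype(float)
    m = env.month_index(date)
    cols["ndvi"] = env.ndvi[:, :, m].ravel()
    for s in ("clay", "sand", "silt"):
        cols[s] = getattr(env, s).ravel()

    lon2d, lat2d = np.meshgrid(env.lons, env.lats)
    doy = float(pd.Timestamp(date).dayofyear)
    cols["daylength_h"] = _daylength_vec(lat2d.ravel(), np.full(ny * nx, doy))
    keep = [c for c in default_catalog().candidates]
    out = pd.DataFrame({k: cols[k] for k in keep})
    out["lon"] = lon2d.ravel()
    out["lat"] = lat2d.ravel()
    out["doy"] = doy
    return out


def build_feature_table(
    surveys: pd.DataFrame,
    env: EnvGrid,
    windows: tuple[WindowSpec, WindowSpec] = (SHORT_WINDOW, LONG_WINDOW),
    thresholds: ThresholdSpec = ThresholdSpec(),
    catalog: CovariateCatalog | None = None,
    transform_cfg: TransformConfig = TransformConfig(),
) -> pd.DataFrame:
    """Assemble the modelling table: one row per retained survey with all
    candidate covariates, the transformed response, stage and position.

    Rows with insufficient weather history or negative NDVI are dropped; the
    counts are recorded in ``table.attrs`` (``dropped_history``,
    ``dropped_ndvi``) so that dropped + retained = input rows.
    """
    if catalog is None:
        catalog = default_catalog()
    if "sampled_density" not in surveys.columns:
        raise ValueError(
            "surveys must carry a 'sampled_density' column "
            "(apply the density-class sampling transform first)"
        )
    feats = engineer_rows(
        env,
        surveys["lon"].to_numpy(),
        surveys["lat"].to_numpy(),
        surveys["date"],
        thresholds=thresholds,
        windows=windows,
    )
    feats = feats.reset_index(drop=True)
    surveys = surveys.reset_index(drop=True)
    n_in = len(feats)
    hist_bad = feats["insufficient_history"].to_numpy()
    ndvi_bad = (~hist_bad) & (feats["ndvi"].to_numpy() < 0)
    keep = ~(hist_bad | ndvi_bad)

    table = feats.loc[keep, list(catalog.candidates) + ["lon", "lat", "doy", "date"]]
    table = table.reset_index(drop=True)
    kept = surveys.loc[keep].reset_index(drop=True)
    table["stage"] = kept["stage"].to_numpy()
    table["sampled_density"] = kept["sampled_density"].to_numpy()
    table["response"] = power_transform(
        kept["sampled_density"].to_numpy(), transform_cfg
    )
    if "id" in kept.columns:
        table["id"] = kept["id"].to_numpy()
    if len(table) == 0:
        raise ValueError("no surveys retained after history/NDVI filtering")
    table.attrs["dropped_history"] = int(hist_bad.sum())
    table.attrs["dropped_ndvi"] = int(ndvi_bad.sum())
    table.attrs["n_input"] = n_in
    table.attrs["transform_lambda"] = transform_cfg.lambda_
    return table


# ---------------------------------------------------------------------------
# standardisation (GLM path; the GAM consumes unscaled covariates)


@dataclass(frozen=True)
class ScalingRecord:
    columns: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]


def standardize(
    table: pd.DataFrame,
    columns: list[str] | tuple[str, ...],
    train_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Centre/scale the named columns to mean 0, sd 1 using statistics from
    the training rows only; return the scaled table and the scaling record
    for prediction-time reuse."""
    if table.attrs.get("standardized"):
        raise ValueError("table is already standardized; refusing to rescale")
    if train_mask is None:
        train_mask = np.ones(len(table), dtype=bool)
    train = table.loc[train_mask, list(columns)]
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance column(s) in training data: {zero_var}")
    record = ScalingRecord(
        tuple(columns), tuple(means.to_numpy()), tuple(sds.to_numpy())
    )
    return apply_scaling(table, record), record


def apply_scaling(table: pd.DataFrame, record: ScalingRecord) -> pd.DataFrame:
    """Apply a stored scaling record (e.g. to validation or grid rows).
    Refuses tables already carrying the standardized flag."""
    if table.attrs.get("standardized"):
        raise ValueError("table is already standardized; refusing to rescale")
    out = table.copy()
    for col, m, s in zip(record.columns, record.means, record.sds):
        out[col] = (out[col] - m) / s
    out.attrs = dict(table.attrs)
    out.attrs["standardized"] = True
    return out
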