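"""Synthetic survey and gridded-environment generator.

Emulates the statistical structure of the roadside locust-survey programme
and its gridded environmental drivers so the whole pipeline is testable
without any data download: spatially smooth, temporally AR(1) weather with
sinusoidal seasonal means on a 0.05 degree grid, zero-inflated rain, monthly
NDVI (with occasional slight negatives, so the NDVI filter is exercised),
static soil fractions, and survey records whose latent abundance is additive
on the square-root scale -- the same estimand the downstream GAM fits.

Latent model per survey: eta = eta0 + sum_j f_j(x_j) + spatial(lon, lat)
+ seasonal(doy), clamped below at a small positive floor; mean density
mu = eta^2; realised counts are Gamma-Poisson (negative binomial) over the
sampled area, then binned into ordinal density classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .covariates import engineer_rows
from .density import DEFAULT_SCHEME, DensityClassScheme
from .grids import EnvGrid

__all__ = [
    "SimulationConfig",
    "SurveyRecord",
    "EnvGrid",
    "default_true_effects",
    "generate_env_grid",
    "generate_surveys",
    "seasonal_mean",
    "surveys_to_csv",
    "surveys_from_csv",
]

_SEASON_MONTHS_EXCLUDED = (6, 7, 8)  # austral winter: June, July, August


@dataclass(frozen=True)
class SurveyRecord:
    """One roadside observation (true_density is simulation-only truth)."""

    id: str
    date: pd.Timestamp
    lon: float
    lat: float
    stage: str  # {nymph, adult, none}
    density_class: int
    true_density: float


def default_true_effects() -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Smooth covariate effects on the square-root (eta) scale.

    Shapes echo the field's qualitative findings: abundance peaks at
    intermediate greenness (NDVI ~ 0.25), rises with humidity (vapour
    pressure) and falls under sustained heat.
    """
    return {
        "ndvi": lambda x: 0.40 * (np.exp(-(((x - 0.25) / 0.18) ** 2)) - 0.6),
        "vp_mean_60d": lambda x: 0.02 * (x - 16.0),
        "tmax_mean_60d": lambda x: -0.18 * np.tanh((x - 33.0) / 6.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    bbox is (lon_min, lon_max, lat_min, lat_max) in degrees; date_range is an
    inclusive (start, end) pair of ISO dates.  eta0 is the baseline of the
    latent square-root-scale predictor; its default puts the fraction of
    positive surveys near the ~32% typical of the surveillance programme.
    """

    seed: int = 0
    bbox: tuple[float, float, float, float] = (144.0, 146.0, -32.0, -30.0)
    grid_step: float = 0.05
    date_range: tuple[str, str] = ("2009-09-01", "2010-05-31")
    n_surveys: int = 2000
    season_only: bool = True
    roadside_bias: float = 0.7
    true_effects: dict[str, Callable] = field(default_factory=default_true_effects)
    nb_dispersion: float = 0.5
    class_scheme: DensityClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    # latent-model knobs
    eta0: float = 0.08
    eta_floor: float = 0.05
    spatial_amplitude: float = 0.25
    seasonal_amplitude: float = 0.12
    survey_area_m2: float = 10.0
    p_nymph: float = 0.125
    #: probability a truly occupied site is recorded as absent (detection
    #: failure); excess zeros beyond the NB count model, default off
    zero_inflation: float = 0.0
    # weather-model knobs
    ar1_coef: float = 0.7
    wet_prob: float = 0.30
    n_transects: int = 8

    def __post_init__(self) -> None:
        lon0, lon1, lat0, lat1 = self.bbox
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if not (lon0 < lon1 and lat0 < lat1):
            raise ValueError("bbox must satisfy lon_min < lon_max, lat_min < lat_max")
        if self.n_surveys < 1:
            raise ValueError("n_surveys must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.roadside_bias <= 1.0:
            raise ValueError("roadside_bias must lie in [0, 1]")


# ---------------------------------------------------------------------------
# environment


def seasonal_mean(var: str, doy: np.ndarray) -> np.ndarray:
    """Deterministic sinusoidal seasonal mean of a daily weather variable
    (southern-hemisphere phase: maxima in mid-January, doy ~ 15)."""
    phase = np.cos(2.0 * np.pi * (np.asarray(doy, dtype=float) - 15.0) / 365.25)
    if var == "tmax":
        return 30.0 + 8.0 * phase
    if var == "tmin":
        return 16.0 + 6.0 * phase
    if var == "rad":
        return 22.0 + 7.0 * phase
    if var == "vp":
        return 14.0 + 4.0 * phase
    raise KeyError(f"no seasonal mean defined for {var!r}")


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float = 3.0):
    """Unit-variance spatially smooth noise (Gaussian-filtered white noise,
    renormalised), smoothing over the first two (lat, lon) axes only."""
    z = rng.standard_normal(shape)
    sig = (sigma_cells, sigma_cells) + (0,) * (len(shape) - 2)
    z = ndimage.gaussian_filter(z, sigma=sig, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def _ar1(rng: np.random.Generator, shape, rho: float, sd: float, sigma_cells=3.0):
    """Spatially smooth AR(1)-in-time anomalies with stationary sd `sd`.
    shape = (ny, nx, nt)."""
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    eps = _smooth_field(rng, shape, sigma_cells) * innov_sd
    out = np.empty(shape)
    out[:, :, 0] = _smooth_field(rng, shape[:2], sigma_cells) * sd
    for t in range(1, shape[2]):
        out[:, :, t] = rho * out[:, :, t - 1] + eps[:, :, t]
    return out


def _grid_coords(config: SimulationConfig):
    lon0, lon1, lat0, lat1 = config.bbox
    lons = np.arange(lon0 + config.grid_step / 2, lon1, config.grid_step)
    lats = np.arange(lat0 + config.grid_step / 2, lat1, config.grid_step)
    if len(lons) == 0 or len(lats) == 0:
        raise ValueError("degenerate bbox: zero grid cells")
    return lons, lats


def generate_env_grid(config: SimulationConfig) -> EnvGrid:
    """Deterministic (given seed) synthetic environment satisfying all grid
    invariants; rain is zero-inflated with >= 50% dry days at defaults."""
    lons, lats = _grid_coords(config)
    dates = pd.date_range(config.date_range[0], config.date_range[1], freq="D")
    ny, nx, nt = len(lats), len(lons), len(dates)
    rho = config.ar1_coef
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 0])))

    doy = dates.dayofyear.to_numpy().astype(float)

    lat_grad = (lats[:, None] - lats.mean())[..., None]  # hotter toward the equator
    tmax = (
        seasonal_mean("tmax", doy)[None, None, :]
        - 0.8 * lat_grad
        + 1.5 * _smooth_field(rng, (ny, nx))[..., None]
        + _ar1(rng, (ny, nx, nt), rho, sd=3.0)
    )
    spread = np.clip(
        10.0
        + 2.0 * _smooth_field(rng, (ny, nx))[..., None]
        + _ar1(rng, (ny, nx, nt), rho, sd=1.5),
        0.5,
        None,
    )
    tmin = tmax - spread

    # rain: wet day iff a smooth AR(1) latent exceeds the dry threshold
    latent = _ar1(rng, (ny, nx, nt), rho, sd=1.0)
    z_wet = norm.ppf(1.0 - config.wet_prob)
    amounts = np.exp(0.8 * _ar1(rng, (ny, nx, nt), rho, sd=1.0) + 1.0)
    rain = np.where(latent > z_wet, amounts, 0.0)

    vp = np.clip(
        seasonal_mean("vp", doy)[None, None, :]
        - 8.0
        + 0.55 * tmin
        + _ar1(rng, (ny, nx, nt), rho, sd=1.2),
        0.1,
        None,
    )
    rad = np.clip(
        seasonal_mean("rad", doy)[None, None, :]
        + _ar1(rng, (ny, nx, nt), rho, sd=2.0)
        - 0.25 * np.minimum(rain, 20.0),
        0.0,
        None,
    )

    months = pd.period_range(dates[0], dates[-1], freq="M")
    nm = len(months)
    month_mid_doy = np.array(
        [pd.Timestamp(m.start_time) .dayofyear + 14 for m in months], dtype=float
    )
    ndvi_season = 0.08 * np.cos(2 * np.pi * (month_mid_doy - 60.0) / 365.25)
    ndvi = (
        0.32
        + ndvi_season[None, None, :]
        + 0.10 * _smooth_field(rng, (ny, nx, nm), sigma_cells=4.0)
    )
    ndvi = np.clip(ndvi, -0.19, 1.0)

    g = np.exp(0.6 * _smooth_field(rng, (ny, nx, 3), sigma_cells=5.0))
    # mineral fractions sum to slightly less than 1 (organic/other remainder),
    # with spatial variation so no fraction is an exact linear combination
    total = np.clip(0.90 + 0.05 * _smooth_field(rng, (ny, nx), sigma_cells=5.0), 0.7, 0.98)
    g = g / g.sum(axis=2, keepdims=True) * total[..., None]
    clay, sand, silt = g[..., 0], g[..., 1], g[..., 2]

    grid = EnvGrid(
        lons=lons, lats=lats, dates=dates,
        tmax=tmax, tmin=tmin, rain=rain, vp=vp, rad=rad,
        months=months, ndvi=ndvi, clay=clay, sand=sand, silt=silt,
    )
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# surveys


def _transect_points(rng: np.random.Generator, config: SimulationConfig, n: int):
    """Sample n locations along synthetic piecewise-linear transects with
    ~10 km (~0.09 degree) spacing, emulating road-following survey routes."""
    lon0, lon1, lat0, lat1 = config.bbox
    pts = []
    for _ in range(config.n_transects):
        x, y = rng.uniform(lon0, lon1), rng.uniform(lat0, lat1)
        heading = rng.uniform(0, 2 * np.pi)
        for _seg in range(3):  # piecewise-linear: a few bends per transect
            seg_len = rng.uniform(0.3, 1.0)
            n_stops = max(int(seg_len / 0.09), 1)
            for s in range(n_stops):
                px = x + np.cos(heading) * 0.09 * s
                py = y + np.sin(heading) * 0.09 * s
                pts.append((px, py))
            x += np.cos(heading) * 0.09 * n_stops
            y += np.sin(heading) * 0.09 * n_stops
            heading += rng.uniform(-0.8, 0.8)
    pts = np.array(pts)
    pts[:, 0] = np.clip(pts[:, 0], lon0 + 1e-6, lon1 - 1e-6)
    pts[:, 1] = np.clip(pts[:, 1], lat0 + 1e-6, lat1 - 1e-6)
    take = rng.integers(0, len(pts), size=n)
    jitter = rng.normal(0.0, 0.005, size=(n, 2))
    out = pts[take] + jitter
    out[:, 0] = np.clip(out[:, 0], lon0 + 1e-6, lon1 - 1e-6)
    out[:, 1] = np.clip(out[:, 1], lat0 + 1e-6, lat1 - 1e-6)
    return out


def _spatial_hotspot(config: SimulationConfig, lon, lat):
    """Fixed Gaussian hotspot contribution to eta (centre at 40% of the bbox
    diagonal; scale ~ a quarter of the box)."""
    lon0, lon1, lat0, lat1 = config.bbox
    cx = lon0 + 0.4 * (lon1 - lon0)
    cy = lat0 + 0.4 * (lat1 - lat0)
    sx = 0.25 * (lon1 - lon0)
    sy = 0.25 * (lat1 - lat0)
    return config.spatial_amplitude * np.exp(
        -(((lon - cx) / sx) ** 2 + ((lat - cy) / sy) ** 2)
    )


def latent_eta(config: SimulationConfig, env: EnvGrid, lons, lats, dates) -> np.ndarray:
    """The generator's latent square-root-scale predictor at arbitrary rows
    (used both for survey generation and for truth-recovery checks)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    eta = np.full(len(lons), config.eta0)
    cov_names = [k for k in config.true_effects if k not in ("lon", "lat", "doy")]
    if cov_names:
        feats = engineer_rows(env, lons, lats, dates)
        if feats["insufficient_history"].any():
            raise ValueError("latent_eta requires 60 days of weather history")
        for name in cov_names:
            eta = eta + config.true_effects[name](feats[name].to_numpy())
    for name in ("lon", "lat", "doy"):
        if name in config.true_effects:
            x = {"lon": lons, "lat": lats, "doy": doy}[name]
            eta = eta + config.true_effects[name](x)
    if config.spatial_amplitude != 0.0:
        eta = eta + _spatial_hotspot(config, lons, lats)
    if config.seasonal_amplitude != 0.0:
        eta = eta + config.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - 30.0) / 365.25
        )
    return np.maximum(eta, config.eta_floor)


def generate_surveys(config: SimulationConfig, env: EnvGrid) -> pd.DataFrame:
    """Generate survey records: clustered roadside locations, Sep-May dates
    when season_only, Gamma-Poisson (negative binomial) densities from the
    latent eta surface, binned into the ordinal class scheme."""
    if config.class_scheme is None:
        raise ValueError("config.class_scheme is required to bin densities")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 1])))
    n = config.n_surveys

    longest_hist = 60
    candidate_dates = env.dates[longest_hist:]
    if config.season_only:
        keep = ~candidate_dates.month.isin(_SEASON_MONTHS_EXCLUDED)
        candidate_dates = candidate_dates[keep]
    if len(candidate_dates) == 0:
        raise ValueError("no admissible survey dates in date_range")
    dates = pd.DatetimeIndex(rng.choice(candidate_dates.to_numpy(), size=n))

    lon0, lon1, lat0, lat1 = config.bbox
    on_road = rng.uniform(size=n) < config.roadside_bias
    road_pts = _transect_points(rng, config, int(on_road.sum()))
    lons = np.where(on_road, 0.0, rng.uniform(lon0, lon1, size=n))
    lats = np.where(on_road, 0.0, rng.uniform(lat0, lat1, size=n))
    lons[on_road] = road_pts[:, 0]
    lats[on_road] = road_pts[:, 1]
    lons = np.round(lons, 2)  # locations recorded to 0.01 degree
    lats = np.round(lats, 2)
    lons = np.clip(lons, lon0, lon1)
    lats = np.clip(lats, lat0, lat1)

    eta = latent_eta(config, env, lons, lats, dates)
    mu = eta**2

    theta = config.nb_dispersion
    area = config.survey_area_m2
    gamma = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(gamma * area)
    if config.zero_inflation > 0.0:
        counts = np.where(
            rng.uniform(size=n) < config.zero_inflation, 0, counts
        )
    true_density = counts / area

    codes = config.class_scheme.classify_array(true_density)
    stage = np.where(
        codes == 0,
        "none",
        np.where(rng.uniform(size=n) < config.p_nymph, "nymph", "adult"),
    )

    return pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "date": dates,
            "lon": lons,
            "lat": lats,
            "stage": stage,
            "density_class": codes.astype(int),
            "true_density": true_density,
        }
    )


# ---------------------------------------------------------------------------
# survey I/O


def surveys_to_csv(surveys: pd.DataFrame, path: str | Path, include_truth=False):
    cols = ["id", "date", "lon", "lat", "stage", "density_class"]
    if include_truth and "true_density" in surveys.columns:
        cols.append("true_density")
    if "sampled_density" in surveys.columns:
        cols.append("sampled_density")
    out = surveys[cols].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out["lon"] = out["lon"].round(2)
    out["lat"] = out["lat"].round(2)
    out.to_csv(path, index=False)


def surveys_from_csv(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path, parse_dates=["date"])
    out["density_class"] = out["density_class"].astype(int)
    return out
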