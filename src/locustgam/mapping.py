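"""Gridded abundance prediction, combined uncertainty, the 50-km
survey-proximity mask, bivariate estimate/uncertainty classification and the
gridded RMSE diagnostic.

Total prediction variance on the density scale combines (a) the model's
standard error propagated through the square-root link and the power
back-transform by the delta method, and (b) the variance injected by the
stochastic class-to-density sampling, estimated by Monte Carlo at the
predicted class.  Cells farther than 50 km (great-circle) from any
ever-surveyed site are masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import engineer_grid
from .density import DensityClassScheme, inverse_power_transform, sample_densities
from .gam import NegativeBinomialGAM
from .grids import EnvGrid

__all__ = [
    "EARTH_RADIUS_KM",
    "PredictionGrid",
    "haversine_km",
    "proximity_mask",
    "predict_grid",
    "bivariate_classify",
    "rmse_map",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km) on a spherical Earth."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def proximity_mask(
    cell_lons, cell_lats, site_lons, site_lats, radius_km: float = 50.0
) -> np.ndarray:
    """True (masked) where a cell lies farther than radius_km from every
    ever-surveyed site; depends only on the site set, not on date."""
    cell_lons = np.asarray(cell_lons, dtype=float).ravel()
    cell_lats = np.asarray(cell_lats, dtype=float).ravel()
    site_lons = np.asarray(site_lons, dtype=float).ravel()
    site_lats = np.asarray(site_lats, dtype=float).ravel()
    if site_lons.size == 0:
        raise ValueError("site list must be non-empty")
    masked = np.ones(cell_lons.shape, dtype=bool)
    # chunk over sites to bound memory on large grids
    step = max(1, int(2e7 // max(cell_lons.size, 1)))
    for s in range(0, site_lons.size, step):
        d = haversine_km(
            cell_lons[:, None], cell_lats[:, None],
            site_lons[None, s : s + step], site_lats[None, s : s + step],
        )
        masked &= d.min(axis=1) > radius_km
    return masked


@dataclass
class PredictionGrid:
    """Per-cell abundance estimate and uncertainty for one date.

    estimate: individuals/m^2; uncertainty_fraction = combined SE / estimate;
    masked: beyond the survey-proximity radius; density_bin/uncertainty_bin:
    tercile classes in {1,2,3} (0 where masked / unclassified).
    """

    date: pd.Timestamp
    lons: np.ndarray
    lats: np.ndarray
    estimate: np.ndarray
    uncertainty_fraction: np.ndarray
    model_variance: np.ndarray
    sampling_variance: np.ndarray
    masked: np.ndarray
    density_bin: np.ndarray = field(default=None)
    uncertainty_bin: np.ndarray = field(default=None)
    bin_edges: dict = field(default_factory=dict)
    palette: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        lon2, lat2 = np.meshgrid(self.lons, self.lats)
        out = pd.DataFrame(
            {
                "lon": lon2.ravel(),
                "lat": lat2.ravel(),
                "estimate": self.estimate.ravel(),
                "uncertainty_fraction": self.uncertainty_fraction.ravel(),
                "masked": self.masked.ravel(),
            }
        )
        if self.density_bin is not None:
            out["density_bin"] = self.density_bin.ravel()
            out["uncertainty_bin"] = self.uncertainty_bin.ravel()
        return out


def predict_grid(
    model: NegativeBinomialGAM,
    env: EnvGrid,
    date,
    scheme: DensityClassScheme,
    n_uncertainty_draws: int = 200,
    transform_lambda: float | None = 1.0 / 6.0,
    surveyed_sites: pd.DataFrame | None = None,
    radius_km: float = 50.0,
    seed: int = 0,
) -> PredictionGrid:
    """Predict abundance for every grid cell on one date.

    Covariates are engineered per cell exactly as for surveys.  If the model
    was fitted on the power-transformed response, pass its lambda so the
    estimate is mapped back to the density scale (None = model fitted on raw
    densities).
    """
    feats = engineer_grid(env, date)
    eta, mu, se_eta = model.predict_terms(feats)
    dmu_deta = 2.0 * eta
    if transform_lambda is not None:
        est = inverse_power_transform(np.maximum(mu, 0.0), transform_lambda)
        # d(mu^(1/lambda))/d mu, evaluated at the fitted mu
        dD_dmu = (1.0 / transform_lambda) * np.maximum(mu, 0.0) ** (
            1.0 / transform_lambda - 1.0
        )
    else:
        est = np.maximum(mu, 0.0)
        dD_dmu = np.ones_like(mu)
    var_model = (dD_dmu * dmu_deta * se_eta) ** 2

    # class-sampling variance at the predicted class (Monte Carlo, fixed seed)
    var_sampling = np.zeros_like(est)
    if n_uncertainty_draws > 0:
        rng = np.random.default_rng(seed)
        codes = scheme.classify_array(est)
        for code in np.unique(codes):
            if code == 0:
                continue
            draws = sample_densities(
                np.full(n_uncertainty_draws, code), scheme, rng
            )
            var_sampling[codes == code] = float(np.var(draws, ddof=1))

    combined = var_model + var_sampling
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(est > 0, np.sqrt(combined) / est, 0.0)

    ny, nx = len(env.lats), len(env.lons)
    if surveyed_sites is not None:
        lon2, lat2 = np.meshgrid(env.lons, env.lats)
        masked = proximity_mask(
            lon2.ravel(), lat2.ravel(),
            surveyed_sites["lon"], surveyed_sites["lat"], radius_km,
        ).reshape(ny, nx)
    else:
        masked = np.zeros((ny, nx), dtype=bool)

    return PredictionGrid(
        date=pd.Timestamp(date),
        lons=env.lons,
        lats=env.lats,
        estimate=est.reshape(ny, nx),
        uncertainty_fraction=frac.reshape(ny, nx),
        model_variance=var_model.reshape(ny, nx),
        sampling_variance=var_sampling.reshape(ny, nx),
        masked=masked,
    )


def _bivariate_palette(n_bins: int = 3) -> dict:
    """Blue x yellow blending palette: (density_bin, uncertainty_bin) -> hex.
    High density / low uncertainty -> bright blue; low density / high
    uncertainty -> bright yellow; high/high -> grey (blue + yellow)."""
    blue = np.array([0.10, 0.40, 0.80])
    yellow = np.array([0.95, 0.85, 0.10])
    white = np.array([0.93, 0.93, 0.93])
    grey = np.array([0.45, 0.45, 0.45])
    pal = {}
    for d in range(1, n_bins + 1):
        for u in range(1, n_bins + 1):
            fd = (d - 1) / (n_bins - 1)
            fu = (u - 1) / (n_bins - 1)
            rgb = (
                (1 - fd) * (1 - fu) * white
                + fd * (1 - fu) * blue
                + (1 - fd) * fu * yellow
                + fd * fu * grey
            )
            pal[(d, u)] = "#%02x%02x%02x" % tuple(int(round(255 * v)) for v in rgb)
    return pal


def bivariate_classify(grid: PredictionGrid, n_bins: int = 3) -> PredictionGrid:
    """Tercile-bin estimate and uncertainty over unmasked cells and attach
    the bivariate class indices and palette.  Masked cells get bin 0."""
    unmasked = ~grid.masked
    if unmasked.sum() < n_bins**2:
        raise ValueError(f"need at least {n_bins ** 2} unmasked cells to classify")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = {}
    bins = {}
    for name, fieldv in (("density", grid.estimate),
                         ("uncertainty", grid.uncertainty_fraction)):
        vals = fieldv[unmasked]
        e = np.quantile(vals, qs)
        if np.allclose(vals.max(), vals.min()):
            warnings.warn(
                f"{name} field is constant over unmasked cells; "
                "falling back to a single bin"
            )
            b = np.ones_like(fieldv, dtype=int)
        else:
            b = np.searchsorted(e, fieldv, side="left") + 1
        b = np.where(unmasked, b, 0)
        edges[name] = e.tolist()
        bins[name] = b
    grid.density_bin = bins["density"]
    grid.uncertainty_bin = bins["uncertainty"]
    grid.bin_edges = edges
    grid.palette = _bivariate_palette(n_bins)
    return grid


def rmse_map(
    surveys: pd.DataFrame, cell_size_deg: float = 0.5,
    observed_col: str = "observed", predicted_col: str = "predicted",
) -> pd.DataFrame:
    """Per-cell RMSE of (predicted - observed) on the transformed scale over
    the surveys falling in each cell; cells without surveys are absent."""
    lon = surveys["lon"].to_numpy(dtype=float)
    lat = surveys["lat"].to_numpy(dtype=float)
    resid = (
        surveys[predicted_col].to_numpy(dtype=float)
        - surveys[observed_col].to_numpy(dtype=float)
    )
    cx = np.floor(lon / cell_size_deg).astype(int)
    cy = np.floor(lat / cell_size_deg).astype(int)
    df = pd.DataFrame({"cx": cx, "cy": cy, "sq": resid**2})
    g = df.groupby(["cx", "cy"])["sq"].agg(["mean", "count"]).reset_index()
    g["rmse"] = np.sqrt(g["mean"])
    g["cell_lon"] = (g["cx"] + 0.5) * cell_size_deg
    g["cell_lat"] = (g["cy"] + 0.5) * cell_size_deg
    return g[["cell_lon", "cell_lat", "rmse", "count"]]
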