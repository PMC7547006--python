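"""Regular lat-lon raster stack holding the gridded environmental drivers.

The stack mirrors interpolated national climate products: daily weather on a
0.05 degree grid (max/min temperature in degC, rain in mm/day, vapour pressure
in hPa, incoming shortwave radiation in MJ/m2), monthly NDVI, and static soil
texture fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EnvGrid"]

_DAILY_VARS = ("tmax", "tmin", "rain", "vp", "rad")
_STATIC_VARS = ("clay", "sand", "silt")


@dataclass
class EnvGrid:
    """Gridded environment: daily weather, monthly NDVI, static soils.

    Daily fields have shape ``(n_lat, n_lon, n_days)``; ``ndvi`` has shape
    ``(n_lat, n_lon, n_months)``; soils ``(n_lat, n_lon)``.  Coordinate
    vectors hold cell centres in degrees.
    """

    lons: np.ndarray
    lats: np.ndarray
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    rain: np.ndarray
    vp: np.ndarray
    rad: np.ndarray
    months: pd.PeriodIndex
    ndvi: np.ndarray
    clay: np.ndarray
    sand: np.ndarray
    silt: np.ndarray

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        ny, nx, nt = len(self.lats), len(self.lons), len(self.dates)
        for name in _DAILY_VARS:
            a = getattr(self, name)
            if a.shape != (ny, nx, nt):
                raise ValueError(f"{name} has shape {a.shape}, expected {(ny, nx, nt)}")
        if self.ndvi.shape != (ny, nx, len(self.months)):
            raise ValueError("ndvi shape inconsistent with months")
        for name in _STATIC_VARS:
            if getattr(self, name).shape != (ny, nx):
                raise ValueError(f"{name} must have shape {(ny, nx)}")
        if np.any(self.rain < 0):
            raise ValueError("rain must be >= 0 everywhere")
        if np.any(self.rad < 0):
            raise ValueError("rad must be >= 0 everywhere")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax must be >= tmin cellwise/daywise")
        soils = self.clay + self.sand + self.silt
        if np.any(self.clay < 0) or np.any(self.sand < 0) or np.any(self.silt < 0):
            raise ValueError("soil fractions must be >= 0")
        if np.any(soils > 1.0 + 1e-12):
            raise ValueError("clay + sand + silt must be <= 1 per cell")
        if np.any(self.ndvi <= -0.2) or np.any(self.ndvi > 1.0):
            raise ValueError("ndvi must lie in (-0.2, 1.0]")

    # -- lookups ------------------------------------------------------------

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (
            float(self.lons.min()),
            float(self.lons.max()),
            float(self.lats.min()),
            float(self.lats.max()),
        )

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Indices of the cell whose centre is nearest (Euclidean in degrees);
        ties break toward the lower index (argmin keeps the first minimum)."""
        step_lon = np.min(np.diff(self.lons)) if len(self.lons) > 1 else 0.05
        step_lat = np.min(np.diff(self.lats)) if len(self.lats) > 1 else 0.05
        if not (
            self.lons.min() - step_lon / 2 <= lon <= self.lons.max() + step_lon / 2
            and self.lats.min() - step_lat / 2 <= lat <= self.lats.max() + step_lat / 2
        ):
            raise ValueError(f"site ({lon}, {lat}) outside grid bounds {self.bbox}")
        ix = int(np.argmin(np.abs(self.lons - lon)))
        iy = int(np.argmin(np.abs(self.lats - lat)))
        return iy, ix

    def date_index(self, date) -> int:
        idx = self.dates.get_indexer([pd.Timestamp(date)])[0]
        if idx < 0:
            raise ValueError(f"date {date} not covered by grid calendar")
        return int(idx)

    def month_index(self, date) -> int:
        idx = self.months.get_indexer([pd.Period(pd.Timestamp(date), freq="M")])[0]
        if idx < 0:
            raise ValueError(f"month of {date} not covered by grid")
        return int(idx)

    # -- persistence (per-variable CSV slices + JSON coords) ----------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        coords = {
            "lons": self.lons.tolist(),
            "lats": self.lats.tolist(),
            "dates": [d.strftime("%Y-%m-%d") for d in self.dates],
            "months": [str(m) for m in self.months],
        }
        (path / "coords.json").write_text(json.dumps(coords))
        ny, nx = len(self.lats), len(self.lons)
        for name in _DAILY_VARS + ("ndvi",):
            a = getattr(self, name)
            np.savetxt(path / f"{name}.csv", a.reshape(ny * nx, -1), delimiter=",")
        for name in _STATIC_VARS:
            np.savetxt(path / f"{name}.csv", getattr(self, name), delimiter=",")

    @classmethod
    def from_dir(cls, path: str | Path) -> "EnvGrid":
        path = Path(path)
        coords = json.loads((path / "coords.json").read_text())
        lons = np.asarray(coords["lons"], dtype=float)
        lats = np.asarray(coords["lats"], dtype=float)
        dates = pd.DatetimeIndex(coords["dates"])
        months = pd.PeriodIndex(coords["months"], freq="M")
        ny, nx = len(lats), len(lons)
        kw = {}
        for name in _DAILY_VARS:
            kw[name] = np.loadtxt(path / f"{name}.csv", delimiter=",").reshape(
                ny, nx, len(dates)
            )
        kw["ndvi"] = np.loadtxt(path / "ndvi.csv", delimiter=",").reshape(
            ny, nx, len(months)
        )
        for name in _STATIC_VARS:
            kw[name] = np.loadtxt(path / f"{name}.csv", delimiter=",").reshape(ny, nx)
        grid = cls(lons=lons, lats=lats, dates=dates, months=months, **kw)
        grid.validate()
        return grid
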