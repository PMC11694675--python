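"""The raster grid stack holding environmental layers per timeframe.

The analysis grid is a regular WGS-84 lat/lon raster (default cell size
0.088 deg, cell-center registration).  Two layers are static in time (depth,
slope); seven are dynamic (bottom temperature/salinity/velocity/stress, max
mixed-layer depth, surface temperature/salinity) and carried per named
timeframe.  A boolean validity mask is shared by all layers; invalid cells
hold NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

STATIC_LAYERS = ("depth", "slope")
DYNAMIC_LAYERS = (
    "bottom_temperature",
    "bottom_salinity",
    "bottom_velocity",
    "bottom_stress",
    "max_mld",
    "surface_temperature",
    "surface_salinity",
)
ALL_LAYERS = STATIC_LAYERS + DYNAMIC_LAYERS

#: the seven multi-decadal timeframes of the study period (1871-2085)
DEFAULT_TIMEFRAMES = (
    "1871-1900",
    "1901-1930",
    "1931-1960",
    "1961-1989",
    "1990-2015",
    "2046-2065",
    "2066-2085",
)
PRESENT = "1990-2015"


@dataclass
class EnvGridStack:
    """Environmental layers on a regular lat/lon grid, per timeframe.

    ``static`` maps layer name -> (nlat, nlon) array; ``dynamic`` maps layer
    name -> (ntimeframe, nlat, nlon) array.  ``mask`` is True on valid cells.
    """

    lat: np.ndarray
    lon: np.ndarray
    timeframes: tuple[str, ...]
    static: dict[str, np.ndarray]
    dynamic: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    cell_size: float = 0.088

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.timeframes = tuple(self.timeframes)
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if len(self.timeframes) < 1:
            raise ValueError("need at least one timeframe")
        shape = (len(self.lat), len(self.lon))
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError("mask shape does not match grid axes")
        for name, arr in self.static.items():
            if arr.shape != shape:
                raise ValueError(f"static layer {name!r} has shape {arr.shape}, "
                                 f"expected {shape}")
        dyn_shape = (len(self.timeframes),) + shape
        for name, arr in self.dynamic.items():
            if arr.shape != dyn_shape:
                raise ValueError(f"dynamic layer {name!r} has shape {arr.shape}, "
                                 f"expected {dyn_shape}")

    # -- access -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat), len(self.lon))

    def timeframe_index(self, timeframe: str) -> int:
        try:
            return self.timeframes.index(timeframe)
        except ValueError:
            raise KeyError(f"unknown timeframe {timeframe!r}; "
                           f"have {self.timeframes}") from None

    def layer(self, name: str, timeframe: str | None = None) -> np.ndarray:
        """A (nlat, nlon) view of a layer, NaN outside the mask."""
        if name in self.static:
            arr = self.static[name]
        elif name in self.dynamic:
            if timeframe is None:
                raise ValueError(f"layer {name!r} is dynamic; pass a timeframe")
            arr = self.dynamic[name][self.timeframe_index(timeframe)]
        else:
            raise KeyError(f"no layer named {name!r}")
        out = arr.astype(float).copy()
        out[~self.mask] = np.nan
        return out

    def covariate_matrix(self, timeframe: str,
                         cells: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, 9) covariate matrix over valid cells (row-major order).

        ``cells`` optionally selects flat cell indices; default: all valid.
        """
        if cells is None:
            cells = np.flatnonzero(self.mask.ravel())
        cols = [self.layer(name, timeframe).ravel()[cells] for name in ALL_LAYERS]
        return np.column_stack(cols)

    # -- coordinate helpers ------------------------------------------------
    def cell_index(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell whose center is nearest to each point.

        Points farther than half a cell outside the grid get index -1.
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        half = self.cell_size / 2.0
        i = np.rint((lat - self.lat[0]) / self.cell_size).astype(int)
        j = np.rint((lon - self.lon[0]) / self.cell_size).astype(int)
        bad = ((lat < self.lat[0] - half) | (lat > self.lat[-1] + half)
               | (lon < self.lon[0] - half) | (lon > self.lon[-1] + half))
        i[bad] = -1
        j[bad] = -1
        return i, j

    def flat_index(self, lat, lon) -> np.ndarray:
        i, j = self.cell_index(lat, lon)
        flat = i * len(self.lon) + j
        flat[(i < 0) | (j < 0)] = -1
        return flat

    def cell_center(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        return self.lat[np.asarray(i)], self.lon[np.asarray(j)]

    # -- IO ----------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        """CF-style xarray Dataset (writable to NetCDF with the scipy engine)."""
        data = {}
        for name, arr in self.static.items():
            out = arr.astype(float).copy()
            out[~self.mask] = np.nan
            data[name] = (("lat", "lon"), out)
        for name, arr in self.dynamic.items():
            out = arr.astype(float).copy()
            out[:, ~self.mask] = np.nan
            data[name] = (("timeframe", "lat", "lon"), out)
        data["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds = xr.Dataset(
            data,
            coords={"lat": self.lat, "lon": self.lon,
                    "timeframe": list(self.timeframes)},
            attrs={"cell_size": self.cell_size, "datum": "WGS-84",
                   "registration": "cell-center"},
        )
        ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
        ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EnvGridStack":
        timeframes = tuple(str(t) for t in ds["timeframe"].values)
        static = {n: ds[n].values.copy() for n in STATIC_LAYERS if n in ds}
        dynamic = {n: ds[n].values.copy() for n in DYNAMIC_LAYERS if n in ds}
        mask = (ds["mask"].values.astype(bool) if "mask" in ds
                else np.ones((ds.sizes["lat"], ds.sizes["lon"]), dtype=bool))
        return cls(lat=ds["lat"].values.copy(), lon=ds["lon"].values.copy(),
                   timeframes=timeframes, static=static, dynamic=dynamic,
                   mask=mask, cell_size=float(ds.attrs.get("cell_size", 0.088)))

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvGridStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())
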