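"""Gridded fields and country masks on a regular latitude–longitude grid.

A :class:`GriddedField` is a plain 2-D array with ascending ``lat``/``lon``
coordinate vectors and a unit string; it round-trips through CF-style NetCDF
via xarray.  A :class:`CountryMask` stores, for every country, fractional
per-cell ownership weights — border cells may be split between countries, but
the per-cell weight summed over countries never exceeds one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import ValidationError

_NC_ENGINE = "scipy"  # NetCDF-3 classic; no external netCDF library needed


@dataclass
class GriddedField:
    """A scalar field on a regular lat–lon grid.

    Parameters
    ----------
    lat, lon : 1-D arrays of cell-centre coordinates, strictly ascending,
        in degrees.
    values : 2-D array of shape ``(n_lat, n_lon)``; must be finite.
    units : physical units of ``values`` (e.g. ``"Mg/yr"``, ``"pM"``).
    """

    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lat.ndim != 1 or self.lon.ndim != 1:
            raise ValidationError("lat and lon must be one-dimensional")
        if np.any(np.diff(self.lat) <= 0) or np.any(np.diff(self.lon) <= 0):
            raise ValidationError("lat and lon must be strictly ascending")
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({self.lat.size}, {self.lon.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("field values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def global_sum(self) -> float:
        return float(self.values.sum())

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "GriddedField":
        return GriddedField(self.lat, self.lon, values, self.units if units is None else units)

    def same_grid(self, other: "GriddedField") -> bool:
        return (
            self.lat.shape == other.lat.shape
            and self.lon.shape == other.lon.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def require_same_grid(self, other: "GriddedField") -> None:
        if not self.same_grid(other):
            raise ValidationError("grids do not match")

    def to_dataarray(self, name: str = "field") -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("lat", "lon"),
            coords={"lat": self.lat, "lon": self.lon},
            name=name,
            attrs={"units": self.units},
        )
        da.lat.attrs.update(units="degrees_north", standard_name="latitude")
        da.lon.attrs.update(units="degrees_east", standard_name="longitude")
        return da

    @classmethod
    def from_dataarray(cls, da: xr.DataArray) -> "GriddedField":
        return cls(
            np.asarray(da["lat"].values),
            np.asarray(da["lon"].values),
            np.asarray(da.values),
            str(da.attrs.get("units", "")),
        )

    def to_netcdf(self, path, name: str = "field") -> None:
        self.to_dataarray(name).to_netcdf(path, engine=_NC_ENGINE)

    @classmethod
    def from_netcdf(cls, path, name: str | None = None) -> "GriddedField":
        with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
            da = ds[name] if name is not None else ds[next(iter(ds.data_vars))]
            return cls.from_dataarray(da.load())


@dataclass
class CountryMask:
    """Fractional per-country ownership weights on a lat–lon grid.

    ``weights`` maps country code → 2-D array in [0, 1]; summed over
    countries, no cell may exceed 1 (a cell can be partly unowned — ocean or
    unclaimed — but never over-owned, so rescaling by country totals cannot
    double-count emissions).
    """

    lat: np.ndarray
    lon: np.ndarray
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        shape = (self.lat.size, self.lon.size)
        total = np.zeros(shape)
        for code, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != shape:
                raise ValidationError(f"mask for {code!r} has shape {w.shape}, expected {shape}")
            if np.any(w < 0) or np.any(w > 1 + 1e-12):
                raise ValidationError(f"mask weights for {code!r} outside [0, 1]")
            self.weights[code] = w
            total += w
        if np.any(total > 1 + 1e-9):
            raise ValidationError("per-cell mask weights sum to more than 1")

    @property
    def countries(self) -> list[str]:
        return list(self.weights)

    def total_weight(self) -> np.ndarray:
        shape = (self.lat.size, self.lon.size)
        out = np.zeros(shape)
        for w in self.weights.values():
            out += w
        return out

    def country_sum(self, f: GriddedField, code: str) -> float:
        """Mask-weighted sum of ``f`` over one country."""
        if f.values.shape != (self.lat.size, self.lon.size):
            raise ValidationError("field shape does not match mask grid")
        return float((f.values * self.weights[code]).sum())

    def to_dataset(self) -> xr.Dataset:
        arr = np.stack([self.weights[c] for c in self.countries]) if self.weights else np.zeros(
            (0, self.lat.size, self.lon.size)
        )
        return xr.Dataset(
            {"weights": (("country", "lat", "lon"), arr)},
            coords={"country": self.countries, "lat": self.lat, "lon": self.lon},
        )

    def to_netcdf(self, path) -> None:
        ds = self.to_dataset()
        # NetCDF-3 stores strings as char arrays; keep codes plain ASCII
        ds = ds.assign_coords(country=[str(c) for c in ds["country"].values])
        ds.to_netcdf(path, engine=_NC_ENGINE)

    @classmethod
    def from_netcdf(cls, path) -> "CountryMask":
        with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
            ds = ds.load()
            codes = [
                c.decode() if isinstance(c, bytes) else str(c) for c in ds["country"].values
            ]
            weights = {c: np.asarray(ds["weights"].values[i]) for i, c in enumerate(codes)}
            return cls(np.asarray(ds["lat"].values), np.asarray(ds["lon"].values), weights)
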