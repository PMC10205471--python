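"""Linear source–receptor surrogate for mercury fate and transport.

A full chemistry–transport simulation resolves atmospheric redox chemistry,
ocean circulation and the soil pool; for scenario *differencing*, the
essential structure is (i) linearity of the environmental response in
emissions and (ii) a latitude-dependent deposited fraction — atmospheric
oxidation, which converts long-lived Hg⁰ to rapidly depositing Hgᴵᴵ, is
fastest near the 40° band and slowest at the equator, so relocating
emissions poleward raises global deposition and equatorward lowers it.

The surrogate maps a gridded emission field to three environmental fields
through one annual-mean linear operator:

* **deposition** ``D``: each source cell deposits a fraction ``α(lat)``
  locally (split over the source cell and a few downwind cells with
  exponentially decaying shares, eastward by default), plus a
  ``global_mixing`` fraction spread uniformly over the globe; the remainder
  stays in the long-lived global pool and is reported explicitly, not lost;
* **plankton MeHg** ``P``: ocean cells respond linearly to the local
  deposition anomaly with gain ``plankton_gain``, because marine MeHg is
  methylated from deposited inorganic mercury;
* **soil Hg** ``S``: a heavily damped multiplicative response
  (``soil_gain`` ≪ 1) on top of a large background, reflecting the soil
  reservoir's mass and lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import xarray as xr

from .errors import ConfigurationError, ValidationError
from .grids import _NC_ENGINE, GriddedField


@dataclass(frozen=True)
class TransportParams:
    """Parameters of the source–receptor operator.

    ``local_fraction_min``/``local_fraction_peak`` are the deposited
    fractions at the equator and at ``peak_latitude``; ``advection_cells``
    downwind cells share the local deposit with exponential decay rate
    ``advection_decay`` per cell; ``global_mixing`` is deposited uniformly
    everywhere.  ``deposition_norm`` (Mg/yr per cell) normalises the soil
    response so it stays linear; backgrounds are natural + legacy levels,
    identical across scenarios.
    """

    local_fraction_peak: float = 0.6
    local_fraction_min: float = 0.2
    peak_latitude: float = 40.0
    advection_cells: int = 3
    advection_decay: float = 1.0
    global_mixing: float = 0.1
    plankton_gain: float = 0.05  # pM per (Mg/yr per cell) deposition anomaly
    soil_gain: float = 0.005  # dimensionless, < 0.01
    deposition_norm: float = 1.0  # Mg/yr per cell
    background_D: float = 0.5  # Mg/yr per cell
    background_P: float = 1.0  # pM
    background_S: float = 50.0  # ng/g
    downwind_direction: int = 1  # +1 → east (+lon), −1 → west

    def validate(self) -> None:
        for name in ("local_fraction_peak", "local_fraction_min", "global_mixing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.local_fraction_min > self.local_fraction_peak:
            raise ConfigurationError(
                "local_fraction_min must not exceed local_fraction_peak"
            )
        if self.local_fraction_peak + self.global_mixing > 1 + 1e-12:
            raise ConfigurationError(
                "per-source deposited shares exceed 1: "
                "local_fraction_peak + global_mixing must be ≤ 1"
            )
        if self.advection_cells < 0:
            raise ConfigurationError("advection_cells must be nonnegative")
        if self.peak_latitude <= 0:
            raise ConfigurationError("peak_latitude must be positive")
        if not 0 <= self.soil_gain:
            raise ConfigurationError("soil_gain must be nonnegative")
        if self.deposition_norm <= 0:
            raise ConfigurationError("deposition_norm must be positive")
        if self.downwind_direction not in (-1, 1):
            raise ConfigurationError("downwind_direction must be +1 or -1")


@dataclass
class EnvironmentalFields:
    """Deposition (Mg/yr per cell), plankton MeHg (pM, ocean only) and soil
    Hg (ng/g) under one emission scenario."""

    D: GriddedField
    P: GriddedField
    S: GriddedField


@dataclass
class TransferOperator:
    """Linear map from a gridded emission field to environmental fields.

    The operator is applied component-wise (local/advected, globally mixed)
    rather than as a dense matrix; ``column`` materialises the response to a
    unit source where needed.
    """

    lat: np.ndarray
    lon: np.ndarray
    params: TransportParams
    ocean: np.ndarray  # 0/1 per cell

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.ocean = np.asarray(self.ocean, dtype=float)
        if self.ocean.shape != (self.lat.size, self.lon.size):
            raise ValidationError("ocean mask shape does not match the grid")
        self.params.validate()

    # ---- deposited-fraction geometry -----------------------------------
    def alpha(self) -> np.ndarray:
        """Locally deposited fraction per latitude row, ramping linearly in
        |lat| from ``local_fraction_min`` at the equator to
        ``local_fraction_peak`` at ``peak_latitude`` (clamped beyond)."""
        p = self.params
        frac = np.clip(np.abs(self.lat) / p.peak_latitude, 0.0, 1.0)
        return p.local_fraction_min + (p.local_fraction_peak - p.local_fraction_min) * frac

    def downwind_weights(self) -> np.ndarray:
        p = self.params
        d = np.arange(p.advection_cells + 1, dtype=float)
        w = np.exp(-p.advection_decay * d)
        return w / w.sum()

    def deposited_share(self) -> np.ndarray:
        """Total deposited fraction per source cell: α(lat) + global_mixing."""
        return self.alpha()[:, None] + self.params.global_mixing * np.ones(
            (self.lat.size, self.lon.size)
        )

    # ---- application ----------------------------------------------------
    def deposition_anomaly(self, emissions: np.ndarray) -> np.ndarray:
        """Deposition response (Mg/yr per cell) to an emission field."""
        emissions = np.asarray(emissions, dtype=float)
        if emissions.shape != (self.lat.size, self.lon.size):
            raise ValidationError("emission field shape does not match the operator grid")
        p = self.params
        local = emissions * self.alpha()[:, None]
        out = np.zeros_like(emissions)
        for d, w in enumerate(self.downwind_weights()):
            out += w * np.roll(local, p.downwind_direction * d, axis=1)
        n_cells = emissions.size
        out += p.global_mixing * emissions.sum() / n_cells
        return out

    def budget(self, emissions: np.ndarray) -> dict[str, float]:
        """Mass ledger: emitted = deposited + retained-in-pool."""
        emissions = np.asarray(emissions, dtype=float)
        deposited = float((emissions * self.deposited_share()).sum())
        emitted = float(emissions.sum())
        return {
            "emitted": emitted,
            "deposited": deposited,
            "undeposited": emitted - deposited,
        }

    def column(self, i: int, j: int) -> np.ndarray:
        """Deposition response to a unit source in cell (i, j)."""
        e = np.zeros((self.lat.size, self.lon.size))
        e[i, j] = 1.0
        return self.deposition_anomaly(e)

    def with_deposition_norm(self, emissions: GriddedField) -> "TransferOperator":
        """Freeze the soil normalisation scale to the peak deposition anomaly
        of a reference emission field (use the with-trade inventory so both
        scenarios share one scale)."""
        anom = self.deposition_anomaly(emissions.values)
        norm = float(np.abs(anom).max())
        if norm <= 0:
            raise ValidationError("reference emissions produce no deposition")
        return replace(self, params=replace(self.params, deposition_norm=norm))

    # ---- serialization --------------------------------------------------
    def to_netcdf(self, path) -> None:
        p = self.params
        ds = xr.Dataset(
            {
                "alpha": (("lat",), self.alpha()),
                "downwind_weights": (("cell",), self.downwind_weights()),
                "ocean": (("lat", "lon"), self.ocean),
            },
            coords={"lat": self.lat, "lon": self.lon},
            attrs={k: getattr(p, k) for k in p.__dataclass_fields__},
        )
        ds.to_netcdf(path, engine=_NC_ENGINE)

    @classmethod
    def from_netcdf(cls, path) -> "TransferOperator":
        with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
            ds = ds.load()
            kwargs = {
                k: (int(v) if k in ("advection_cells", "downwind_direction") else float(v))
                for k, v in ds.attrs.items()
            }
            return cls(
                np.asarray(ds["lat"].values),
                np.asarray(ds["lon"].values),
                TransportParams(**kwargs),
                np.asarray(ds["ocean"].values),
            )


def build_operator(
    grid: GriddedField, params: TransportParams, ocean: GriddedField | None = None
) -> TransferOperator:
    """Build the operator on the coordinates of ``grid``; ``ocean`` marks the
    cells carrying a plankton response (all-ocean if omitted)."""
    params.validate()
    if ocean is not None:
        grid.require_same_grid(ocean)
        ocean_values = ocean.values
    else:
        ocean_values = np.ones(grid.shape)
    return TransferOperator(grid.lat, grid.lon, params, ocean_values)


def apply_operator(op: TransferOperator, emissions: GriddedField) -> EnvironmentalFields:
    """Environmental fields for one emission scenario.

    ``D = background_D + op·E``; ``P = ocean · (background_P +
    plankton_gain · op·E)``; ``S = background_S · (1 + soil_gain ·
    op·E / deposition_norm)``.  All three anomalies are linear in ``E``.
    """
    if emissions.lat.size != op.lat.size or emissions.lon.size != op.lon.size:
        raise ValidationError("emission grid does not match the operator grid")
    p = op.params
    anom = op.deposition_anomaly(emissions.values)
    D = GriddedField(op.lat, op.lon, p.background_D + anom, units="Mg/yr")
    P = GriddedField(
        op.lat, op.lon, op.ocean * (p.background_P + p.plankton_gain * anom), units="pM"
    )
    S = GriddedField(
        op.lat,
        op.lon,
        p.background_S * (1.0 + p.soil_gain * anom / p.deposition_norm),
        units="ng/g",
    )
    return EnvironmentalFields(D=D, P=P, S=S)
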