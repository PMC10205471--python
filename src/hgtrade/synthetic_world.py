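"""Self-consistent synthetic worlds for the trade–mercury–health chain.

The generator emulates the *shapes* of the data the real assessment consumes
— a multiregional input–output economy, sectoral mercury emissions, a gridded
emission inventory with country masks, per-country diets and methylmercury
concentrations, and demographics — with the statistical structure the
analysis assumes:

* emission intensities are log-normal per sector, multiplied by a per-region
  development factor, so developing regions are dirtier per unit output by a
  configurable ``intensity_gap`` (the driver of embodied-emission transfers);
* a configurable ``trade_share`` of both intermediate and final demand is
  sourced abroad, so autarky (``trade_share = 0``) is an exact limit;
* countries occupy contiguous longitude strips, developed ones centred near
  the 40° latitude band of fast atmospheric oxidation and developing ones
  near the equator, so trade relocates emissions across the deposition
  gradient exactly as the mechanism under study requires;
* coastal countries eat seafood caught in nearby ocean cells, inland ones
  eat rice and freshwater fish.

Nothing here mimics real-world magnitudes; every downstream identity
(balance, conservation, linearity) holds by construction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .grids import CountryMask, GriddedField
from .mrio import EmissionAccount, MRIOTable, spectral_radius

_MAX_RESCALE = 50


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    ``trade_share`` is the fraction of each region's intermediate and final
    demand sourced abroad; ``intensity_gap`` the ratio of developing to
    developed mean emission intensity; ``coastal_fraction`` the share of
    countries with marine fish catch.
    """

    n_regions: int = 10
    n_sectors: int = 4
    grid_shape: tuple[int, int] = (36, 72)
    trade_share: float = 0.4
    intensity_gap: float = 5.0
    coastal_fraction: float = 0.5
    global_emissions: float = 1833.3  # Mg/yr, global anthropogenic total
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_regions", "n_sectors"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be at least 1")
        n_lat, n_lon = self.grid_shape
        if n_lat < 1 or n_lon < 1:
            raise ConfigurationError("grid_shape entries must be at least 1")
        if n_lon < self.n_regions:
            raise ConfigurationError(
                "grid_shape longitude count must be at least n_regions"
            )
        if not 0 <= self.trade_share < 1:
            raise ConfigurationError("trade_share must lie in [0, 1)")
        if self.intensity_gap < 1:
            raise ConfigurationError("intensity_gap must be at least 1")
        if not 0 <= self.coastal_fraction <= 1:
            raise ConfigurationError("coastal_fraction must lie in [0, 1]")
        if self.global_emissions <= 0:
            raise ConfigurationError("global_emissions must be positive")


@dataclass
class Demographics:
    """Per-country births, gendered population, baseline fatal-heart-attack
    incidence and GDP per capita."""

    table: pd.DataFrame  # births, pop_male, pop_female, cf_male, cf_female, gdp_pc

    def __post_init__(self) -> None:
        required = {"births", "pop_male", "pop_female", "cf_male", "cf_female", "gdp_pc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"demographics table missing columns {sorted(missing)}")


@dataclass
class SyntheticWorld:
    economy: MRIOTable
    emissions: EmissionAccount
    grid_inventory: GriddedField
    masks: CountryMask
    ocean_mask: GriddedField
    population_grid: GriddedField
    fishcatch: dict[str, np.ndarray]
    diets: pd.DataFrame  # I_seafood, I_fwfish, I_rice (g/day)
    concentrations: pd.DataFrame  # C_seafood, C_fwfish, C_rice (µg/g)
    demographics: Demographics
    country_info: pd.DataFrame  # is_developed, is_coastal, center_lat

    @property
    def regions(self) -> list[str]:
        return list(self.economy.regions)

    def pba_country_totals(self) -> pd.Series:
        return self.emissions.country_totals()

    def to_dir(self, path) -> None:
        """Write the world in plain interchange formats (CSV + NetCDF)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.economy.to_csv_dir(path / "economy")
        idx = self.economy.index()
        pd.DataFrame(
            {"pba": self.emissions.pba, "intensity": self.emissions.intensity},
            index=[f"{r}:{s}" for r, s in idx],
        ).to_csv(path / "emissions.csv")
        self.grid_inventory.to_netcdf(path / "grid_inventory.nc", name="emissions")
        self.masks.to_netcdf(path / "country_masks.nc")
        self.ocean_mask.to_netcdf(path / "ocean_mask.nc", name="ocean")
        self.population_grid.to_netcdf(path / "population.nc", name="population")
        self.diets.to_csv(path / "diets.csv")
        self.concentrations.to_csv(path / "concentrations.csv")
        self.demographics.table.to_csv(path / "demographics.csv")
        self.country_info.to_csv(path / "countries.csv")


def _region_codes(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [letters[i // 26 % 26] + letters[i % 26] + "A" for i in range(n)]


def generate_mrio(
    n_regions: int,
    n_sectors: int,
    trade_share: float,
    seed: int | np.random.Generator,
) -> MRIOTable:
    """Random balanced MRIO economy with a prescribed import share.

    The technical-coefficient matrix is drawn with column sums in
    (0.2, 0.55), so its spectral radius is below one by construction; gross
    output then solves the Leontief system for the drawn final demand and
    ``Z = A · diag(x)`` balances exactly.  A rescale loop (divide ``A`` by
    1.1× its spectral radius) guards the degenerate numerical corner.
    """
    if not 0 <= trade_share < 1:
        raise ConfigurationError("trade_share must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R, S = n_regions, n_sectors
    n = R * S
    regions = _region_codes(R)
    sectors = [f"S{k:02d}" for k in range(S)]

    def sourced(dest: int, total_by_sector: np.ndarray) -> np.ndarray:
        """Spread demand of region `dest` for each product sector over source
        regions: (1 − τ) domestic, τ abroad with random weights."""
        col = np.zeros(n)
        for k in range(S):
            t = total_by_sector[k]
            col[dest * S + k] += (1.0 - trade_share) * t
            if R > 1 and trade_share > 0:
                others = [r for r in range(R) if r != dest]
                w = rng.dirichlet(np.ones(len(others)))
                for wi, r in zip(w, others):
                    col[r * S + k] += trade_share * t * wi
        return col

    # final demand: lognormal per (destination, product sector)
    Y = np.zeros((n, R))
    for s in range(R):
        totals = rng.lognormal(mean=np.log(100.0), sigma=0.4, size=S)
        Y[:, s] = sourced(s, totals)

    # technical coefficients: column sums strictly below 1
    A = np.zeros((n, n))
    for j in range(n):
        dest = j // S
        t_j = rng.uniform(0.2, 0.55)
        shares = rng.dirichlet(np.ones(S)) * t_j
        A[:, j] = sourced(dest, shares)

    for attempt in range(_MAX_RESCALE):
        rho = spectral_radius(A)
        if rho < 1.0 - 1e-9:
            break
        A = A / (1.1 * rho)
    else:
        raise GenerationError("could not rescale A below unit spectral radius")

    x = np.linalg.solve(np.eye(n) - A, Y.sum(axis=1))
    if np.any(x < 0):
        raise GenerationError("generated economy has negative gross output")
    Z = A * x[None, :]
    return MRIOTable(regions, sectors, Z, Y, x)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a full synthetic world; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, S = config.n_regions, config.n_sectors
    n_lat, n_lon = config.grid_shape

    economy = generate_mrio(R, S, config.trade_share, rng)
    regions = economy.regions

    # development split: later half of the index is "developing"
    n_developed = max(1, R // 2) if R > 1 else 1
    is_developed = np.array([i < n_developed for i in range(R)])

    # sectoral log-normal intensities × development multiplier
    base = rng.lognormal(mean=np.log(1e-4), sigma=0.5, size=S)
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(R, S))
    mult = np.where(is_developed, 1.0, config.intensity_gap)
    intensity = (base[None, :] * noise) * mult[:, None]
    pba = intensity.reshape(-1) * economy.x
    pba *= config.global_emissions / pba.sum()  # anchor the global total
    account = EmissionAccount.from_pba(economy, pba)
    pba_totals = account.country_totals()

    # --- grid geometry -------------------------------------------------
    lat = -90.0 + (np.arange(n_lat) + 0.5) * 180.0 / n_lat
    lon = -180.0 + (np.arange(n_lon) + 0.5) * 360.0 / n_lon

    n_coastal = int(round(config.coastal_fraction * R))
    coastal_idx = rng.permutation(R)[:n_coastal]
    is_coastal = np.zeros(R, dtype=bool)
    is_coastal[coastal_idx] = True

    strip_edges = np.linspace(0, n_lon, R + 1).astype(int)
    center_lat = np.where(is_developed, 40.0, 0.0) + rng.uniform(-5, 5, size=R)
    half_band = 15.0

    masks: dict[str, np.ndarray] = {}
    for i, code in enumerate(regions):
        w = np.zeros((n_lat, n_lon))
        rows = np.flatnonzero(np.abs(lat - center_lat[i]) <= half_band)
        if rows.size == 0:
            rows = np.array([int(np.argmin(np.abs(lat - center_lat[i])))])
        cols = slice(strip_edges[i], strip_edges[i + 1])
        w[rows[0] : rows[-1] + 1, cols] = 1.0
        if rows.size >= 3:  # fractional border rows
            w[rows[0], cols] = 0.5
            w[rows[-1], cols] = 0.5
        masks[code] = w
    mask = CountryMask(lat, lon, masks)
    land = mask.total_weight()
    ocean = GriddedField(lat, lon, (land < 1.0 - 1e-12).astype(float), units="1")

    # gridded emissions: random within-country pattern, mask-weighted sums
    # matching the PBA country totals exactly
    inventory = np.zeros((n_lat, n_lon))
    for i, code in enumerate(regions):
        w = masks[code]
        cells = w > 0
        pattern = np.zeros((n_lat, n_lon))
        pattern[cells] = rng.lognormal(mean=0.0, sigma=0.6, size=int(cells.sum()))
        denom = float((pattern * w).sum())
        inventory += pattern * (pba_totals[code] / denom)
    grid_inventory = GriddedField(lat, lon, inventory, units="Mg/yr")

    # population on land cells
    pop = np.zeros((n_lat, n_lon))
    for code in regions:
        w = masks[code]
        cells = w > 0
        pop[cells] += rng.lognormal(mean=np.log(2e6), sigma=0.8, size=int(cells.sum()))
    population_grid = GriddedField(lat, lon, pop, units="persons")

    # fish catch: coastal countries fish the ocean cells of their own strip
    fishcatch: dict[str, np.ndarray] = {}
    for i, code in enumerate(regions):
        if not is_coastal[i]:
            continue
        w = np.zeros((n_lat, n_lon))
        cols = slice(strip_edges[i], strip_edges[i + 1])
        sea = ocean.values[:, cols] > 0
        if not sea.any():
            continue
        raw = np.zeros_like(sea, dtype=float)
        raw[sea] = rng.dirichlet(np.ones(int(sea.sum())))
        w[:, cols] = raw
        fishcatch[code] = w

    # diets: coastal → seafood-heavy, inland → rice/freshwater-fish-heavy
    jitter = lambda base, n: base * rng.lognormal(0.0, 0.25, size=n)  # noqa: E731
    diets = pd.DataFrame(index=pd.Index(regions, name="region"))
    diets["I_seafood"] = np.where(
        [c in fishcatch for c in regions], jitter(60.0, R), 0.0
    )
    diets["I_fwfish"] = np.where(is_coastal, jitter(20.0, R), jitter(40.0, R))
    diets["I_rice"] = np.where(is_coastal, jitter(60.0, R), jitter(300.0, R))
    conc = pd.DataFrame(index=diets.index)
    conc["C_seafood"] = jitter(0.10, R)
    conc["C_fwfish"] = jitter(0.05, R)
    conc["C_rice"] = jitter(0.005, R)

    # demographics from the population grid
    country_pop = np.array([float((pop * masks[c]).sum()) for c in regions])
    male_share = rng.uniform(0.48, 0.52, size=R)
    demo = pd.DataFrame(index=diets.index)
    demo["births"] = country_pop * rng.uniform(0.009, 0.015, size=R)
    demo["pop_male"] = country_pop * male_share
    demo["pop_female"] = country_pop * (1 - male_share)
    demo["cf_male"] = rng.uniform(0.001, 0.003, size=R)
    demo["cf_female"] = rng.uniform(0.0008, 0.002, size=R)
    demo["gdp_pc"] = np.where(is_developed, jitter(40000.0, R), jitter(8000.0, R))

    info = pd.DataFrame(
        {"is_developed": is_developed, "is_coastal": is_coastal, "center_lat": center_lat},
        index=diets.index,
    )

    return SyntheticWorld(
        economy=economy,
        emissions=account,
        grid_inventory=grid_inventory,
        masks=mask,
        ocean_mask=ocean,
        population_grid=population_grid,
        fishcatch=fishcatch,
        diets=diets,
        concentrations=conc,
        demographics=Demographics(demo),
        country_info=info,
    )
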