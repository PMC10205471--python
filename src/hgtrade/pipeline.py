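"""End-to-end orchestration: world → footprint → scenario → transport →
exposure → health → uncertainty.

One global seed fans out deterministically to per-module seeds via a CRC-32
hash of the module name (documented so another implementation can reproduce
the *structure* of a run; bit-level identity is only guaranteed within one
implementation).  Every stage's outputs are written in plain formats (CSV,
NetCDF, JSON) and logged with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import exposure as expo
from . import mrio
from .errors import ConfigurationError
from .health import TABLE1_ROWS, HealthParams, ImpactTable, scenario_impacts
from .scenarios import no_trade_inventory, scenario_delta
from .synthetic_world import SyntheticWorld, WorldConfig, generate_world
from .transport import TransportParams, apply_operator, build_operator
from .uncertainty import IntervalResult, UncertaintySpec, run_monte_carlo

logger = logging.getLogger(__name__)


def derive_seed(seed: int, module: str) -> int:
    """Deterministic per-module seed: ``(seed * 1000003 + crc32(module)) mod 2³¹``."""
    return (seed * 1000003 + zlib.crc32(module.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    world: WorldConfig = field(default_factory=WorldConfig)
    transport: TransportParams = field(default_factory=TransportParams)
    health: HealthParams | None = None
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    seed: int = 0
    mc: bool = False
    outdir: Path | None = None

    def validate(self) -> None:
        self.world.validate()
        self.transport.validate()
        if self.health is None:
            raise ConfigurationError("health parameters are required (no defaults exist)")
        self.health.validate()
        self.uncertainty.validate()


def config_from_yaml(path) -> RunConfig:
    """Build a RunConfig from a YAML file with ``world``, ``transport``,
    ``health`` and ``uncertainty`` blocks (all but ``health`` optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    world = WorldConfig(**{**raw.get("world", {})})
    if isinstance(world.grid_shape, list):
        world = replace(world, grid_shape=tuple(world.grid_shape))
    transport = TransportParams(**raw.get("transport", {}))
    health_block = raw.get("health")
    health = None
    if health_block is not None:
        health_block = dict(health_block)
        deflators = {int(k): float(v) for k, v in health_block.pop("deflators", {}).items()}
        for k, v in health_block.items():
            if isinstance(v, str) and k not in ("bw_mode",):
                health_block[k] = float(v)  # YAML 1.1 reads "6.3e6" as a string
        health = HealthParams(**health_block, deflators=deflators or {2005: 1.0, 2008: 1.0})
    unc_block = dict(raw.get("uncertainty", {}))
    if "components" in unc_block:
        unc_block["components"] = {
            k: tuple(v) for k, v in unc_block["components"].items()
        }
    if "percentiles" in unc_block:
        unc_block["percentiles"] = tuple(unc_block["percentiles"])
    uncertainty = UncertaintySpec(**unc_block)
    return RunConfig(
        world=world,
        transport=transport,
        health=health,
        uncertainty=uncertainty,
        seed=int(raw.get("seed", 0)),
        mc=bool(raw.get("mc", False)),
    )


@dataclass
class RunReport:
    """Paths of all written outputs plus the headline summary."""

    outputs: dict[str, Path]
    summary: dict
    world: SyntheticWorld
    impacts: ImpactTable
    intervals: dict[str, IntervalResult] | None = None


def summarize_table1(impacts: ImpactTable) -> pd.DataFrame:
    """Global summary: six quantities × (with_trade, no_trade, net)."""
    return impacts.global_summary()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(outputs: dict[str, Path], key: str, path: Path, writer) -> None:
    writer(path)
    outputs[key] = path
    logger.info("wrote %s (%s, sha256=%s)", key, path, _sha256(path)[:16])


def _mc_targets(summary: pd.DataFrame) -> dict[str, float]:
    return {
        "net_iq_total": float(summary.loc["iq_total", "net"]),
        "net_fha_deaths": float(summary.loc["fha_deaths", "net"]),
        "net_loss_total": float(summary.loc["loss_total", "net"]),
        "wt_loss_total": float(summary.loc["loss_total", "with_trade"]),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain and write all artefacts to ``config.outdir``.

    Stage order and outputs: embodied-flow CSV → scenario NetCDFs →
    environmental-field NetCDFs (both scenarios) → exposure CSV → impact CSV
    (per-country rows + global summary) → optional Monte Carlo intervals →
    JSON summary of global net impacts.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir is not None else Path("hgtrade_run")
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- synthetic world -------------------------------------------------
    world_cfg = replace(config.world, seed=derive_seed(config.seed, "world"))
    world = generate_world(world_cfg)
    logger.info("generated world: %d regions × %d sectors, grid %s",
                world_cfg.n_regions, world_cfg.n_sectors, world.grid_inventory.shape)

    # --- embodied-emission accounting ------------------------------------
    flows = mrio.embodied_flow_matrix(world.emissions, world.economy)
    share = mrio.embodied_trade_share(flows)
    nets = mrio.net_transfers(flows)
    _write(outputs, "embodied_flows", outdir / "embodied_flows.csv",
           lambda p: flows.to_frame().to_csv(p))
    _write(outputs, "net_transfers", outdir / "net_transfers.csv",
           lambda p: nets.to_csv(p))

    # --- counterfactual scenario -----------------------------------------
    pair = no_trade_inventory(
        world.grid_inventory, world.masks, flows.pba_totals(), flows.cba_totals()
    )
    delta = scenario_delta(pair)
    _write(outputs, "grid_with_trade", outdir / "emissions_with_trade.nc",
           lambda p: pair.with_trade.to_netcdf(p, name="emissions"))
    _write(outputs, "grid_no_trade", outdir / "emissions_no_trade.nc",
           lambda p: pair.no_trade.to_netcdf(p, name="emissions"))
    _write(outputs, "grid_delta", outdir / "emissions_delta.nc",
           lambda p: delta.to_netcdf(p, name="delta"))

    # --- transport surrogate ---------------------------------------------
    op = build_operator(world.grid_inventory, config.transport, world.ocean_mask)
    op = op.with_deposition_norm(pair.with_trade)
    fields_wt = apply_operator(op, pair.with_trade)
    fields_nt = apply_operator(op, pair.no_trade)
    for tag, f in (("wt", fields_wt), ("nt", fields_nt)):
        _write(outputs, f"deposition_{tag}", outdir / f"deposition_{tag}.nc",
               lambda p, f=f: f.D.to_netcdf(p, name="deposition"))
        _write(outputs, f"plankton_{tag}", outdir / f"plankton_{tag}.nc",
               lambda p, f=f: f.P.to_netcdf(p, name="plankton_mehg"))
        _write(outputs, f"soil_{tag}", outdir / f"soil_{tag}.nc",
               lambda p, f=f: f.S.to_netcdf(p, name="soil_hg"))

    # --- exposure ---------------------------------------------------------
    env = expo.country_environment(
        fields_wt, fields_nt, world.masks, world.population_grid, world.fishcatch
    )
    e_wt = expo.exposure_with_trade(world.diets, world.concentrations)
    e_nt = expo.exposure_no_trade(world.diets, world.concentrations, env)
    wt_path = expo.pathway_exposures(world.diets, world.concentrations)
    nt_path = expo.no_trade_pathways(world.diets, world.concentrations, env)
    decomposition = expo.exposure_delta_decomposition(wt_path, nt_path)
    exposure_table = pd.concat(
        [e_wt, e_nt, env, decomposition.add_prefix("delta_")], axis=1
    )
    _write(outputs, "exposure", outdir / "exposure.csv", lambda p: exposure_table.to_csv(p))

    # --- health impacts ---------------------------------------------------
    impacts = scenario_impacts(e_wt, e_nt, world.demographics, config.health)
    summary = summarize_table1(impacts)
    _write(outputs, "impacts", outdir / "impacts.csv", lambda p: impacts.table.to_csv(p))
    _write(outputs, "table1", outdir / "global_summary.csv", lambda p: summary.to_csv(p))

    # --- Monte Carlo ------------------------------------------------------
    intervals = None
    if config.mc:
        h0 = config.health

        def evaluator(factors: dict[str, float]) -> dict[str, float]:
            fi = factors.get("food_intake", 1.0)
            fc = factors.get("food_concentration", 1.0)
            fd = factors.get("dose_response", 1.0)
            fv = factors.get("valuation", 1.0)
            diets = world.diets * fi
            conc = world.concentrations * fc
            hp = replace(h0, gamma=h0.gamma * fd, phi=h0.phi * fd,
                         el=h0.el * fv, vsl=h0.vsl * fv)
            ew = expo.exposure_with_trade(diets, conc)
            en = expo.exposure_no_trade(diets, conc, env)
            s = scenario_impacts(ew, en, world.demographics, hp).global_summary()
            return _mc_targets(s)

        spec = replace(config.uncertainty, seed=derive_seed(config.seed, "uncertainty"))
        intervals = run_monte_carlo(evaluator, spec)
        rows = {
            k: {"point": v.point, "lower": v.lower, "upper": v.upper}
            for k, v in intervals.items()
        }
        _write(outputs, "mc_intervals", outdir / "mc_intervals.csv",
               lambda p: pd.DataFrame(rows).T.to_csv(p))

    # --- JSON summary -----------------------------------------------------
    summary_dict = {
        "embodied_trade_share": share,
        "global_pba_Mg": float(world.emissions.total()),
        "global_deposition_wt_Mg": fields_wt.D.global_sum(),
        "global_deposition_nt_Mg": fields_nt.D.global_sum(),
        "net_global_deposition_Mg": fields_wt.D.global_sum() - fields_nt.D.global_sum(),
        "net_global_exposure_ug_day": float((e_wt - e_nt).sum()),
        "table1": {row: {c: float(summary.loc[row, c]) for c in summary.columns}
                   for row in TABLE1_ROWS},
        "n_missing_demographics": impacts.n_missing,
        "seed": config.seed,
    }
    if intervals is not None:
        summary_dict["mc_intervals"] = {
            k: {"point": v.point, "lower": v.lower, "upper": v.upper,
                "relative_bounds_pct": list(v.relative_bounds)}
            for k, v in intervals.items()
        }
    _write(outputs, "summary", outdir / "summary.json",
           lambda p: p.write_text(json.dumps(summary_dict, indent=2)))

    return RunReport(outputs=outputs, summary=summary_dict, world=world,
                     impacts=impacts, intervals=intervals)
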