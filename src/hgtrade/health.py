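"""Health endpoints and economic valuation of methylmercury exposure.

Two endpoints are modelled from total dietary MeHg exposure ``E`` (µg/day):

* **Fetal IQ decrement** — linear, no threshold:
  ``ΔIQ = γ·λ·β · dose`` points per fetus, where ``β`` maps intake to blood
  Hg, ``λ`` blood to hair, ``γ`` hair Hg to IQ loss, and ``dose`` is
  ``E·BW`` or ``E/BW`` depending on the body-weight convention
  (``bw_mode``).
* **Fatal heart attacks (FHA)** — log-linear in the adult population:
  ``ΔCF = Σ_g POP_g·Cf_g·ω·(1 − exp(−φ·λ·β·dose))`` deaths/yr, with
  baseline incidence ``Cf_g`` by gender, dose–response slope ``φ`` and a
  causality probability ``ω``.

Monetisation: ``H = EL·ΔIQ_total + VSL·ΔCF`` in 2020 USD, with ``EL`` the
lifetime earnings loss per IQ point (2008 USD) and ``VSL`` the value of a
statistical life (2005 USD), both brought to 2020 via user-supplied
deflators; the VSL can optionally scale with national GDP per capita.

Note on ``bw_mode``: the multiplicative convention (default) follows the
dose terms above literally; the standard one-compartment intake→blood chain
is usually written per kg body weight, so a ``divide`` option is provided —
choose whichever matches the provenance of your β.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .synthetic_world import Demographics

logger = logging.getLogger(__name__)

TABLE1_ROWS = (
    "iq_per_fetus",
    "iq_total",
    "fha_deaths",
    "loss_iq",
    "loss_fha",
    "loss_total",
)


@dataclass(frozen=True)
class HealthParams:
    """Dose–response and valuation coefficients.

    The dose–response chain (β, λ, γ, φ, ω) has no scientifically neutral
    default; values must come from the user's configuration.
    """

    beta: float  # blood Hg (µg/L) per unit dose
    lambda_: float  # hair Hg (µg/g) per blood Hg (µg/L)
    gamma: float  # IQ points per hair Hg (µg/g)
    phi: float  # FHA log-linear slope per hair Hg (µg/g)
    omega: float  # causality probability, [0, 1]
    bw: float = 70.0  # body weight, kg
    bw_mode: str = "multiply"  # how BW enters the dose: multiply | divide
    el: float = 18832.0  # USD(2008) per IQ point
    vsl: float = 6.3e6  # USD(2005) per death
    deflators: dict[int, float] = field(default_factory=lambda: {2005: 1.0, 2008: 1.0})
    use_country_vsl: bool = False
    vsl_elasticity: float = 1.0  # GDP-per-capita elasticity of the VSL
    vsl_reference_gdp: float = 40000.0  # USD per capita at which vsl applies

    def validate(self) -> None:
        for name in ("beta", "lambda_", "gamma", "phi", "bw", "el", "vsl"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not 0 <= self.omega <= 1:
            raise ConfigurationError("omega must lie in [0, 1]")
        if self.bw_mode not in ("multiply", "divide"):
            raise ConfigurationError("bw_mode must be 'multiply' or 'divide'")
        for year in (2005, 2008):
            if year not in self.deflators:
                raise ConfigurationError(f"missing deflator for base year {year}")

    def dose(self, exposure):
        """Body-weight-adjusted dose term entering both endpoints."""
        e = np.asarray(exposure, dtype=float)
        if np.any(e[np.isfinite(e)] < 0):
            raise ValidationError("exposure must be nonnegative")
        return e * self.bw if self.bw_mode == "multiply" else e / self.bw

    def el_2020(self) -> float:
        return self.el * self.deflators[2008]

    def vsl_2020(self, gdp_pc=None):
        base = self.vsl * self.deflators[2005]
        if not self.use_country_vsl or gdp_pc is None:
            return base
        return base * (np.asarray(gdp_pc, dtype=float) / self.vsl_reference_gdp) ** (
            self.vsl_elasticity
        )


def iq_decrement(exposure, params: HealthParams):
    """Per-fetus IQ decrement (points); linear in exposure, no threshold."""
    params.validate()
    return params.gamma * params.lambda_ * params.beta * params.dose(exposure)


def fha_deaths(exposure, demo: pd.DataFrame, params: HealthParams) -> pd.Series:
    """Fatal-heart-attack deaths per year, summed over genders.

    Bounded above by ``ω·Σ_g POP_g·Cf_g`` for any exposure.
    """
    params.validate()
    x = params.phi * params.lambda_ * params.beta * params.dose(exposure)
    risk = 1.0 - np.exp(-x)
    deaths = (
        demo["pop_male"] * demo["cf_male"] + demo["pop_female"] * demo["cf_female"]
    ) * params.omega * risk
    return deaths.rename("fha_deaths")


def small_dose_limit_check(params: HealthParams, dose: float) -> float:
    """Relative gap between the log-linear FHA response and its linearisation.

    For exponent ``x = φλβ·dose`` the gap is ≈ x/2, so it stays below the
    exponent itself — a second-order sanity bound on the small-dose regime.
    """
    x = params.phi * params.lambda_ * params.beta * dose
    if x == 0:
        return 0.0
    return float(abs((1.0 - np.exp(-x)) - x) / x)


def economic_loss(
    iq_total, deaths, params: HealthParams, gdp_pc=None
) -> dict[str, float]:
    """Monetised loss (2020 USD): ``EL·ΔIQ + VSL·ΔCF``, by component."""
    params.validate()
    loss_iq = params.el_2020() * np.asarray(iq_total, dtype=float)
    loss_fha = params.vsl_2020(gdp_pc) * np.asarray(deaths, dtype=float)
    return {
        "loss_iq": loss_iq,
        "loss_fha": loss_fha,
        "loss_total": loss_iq + loss_fha,
    }


@dataclass
class ImpactTable:
    """Per-country impacts under both scenarios and their net (WT − NT).

    ``table`` columns are ``<quantity>_<wt|nt|net>`` for the six Table-1
    quantities; countries with missing demographics carry NaN rows and are
    excluded from global sums (their count is logged and recorded in
    ``n_missing``).
    """

    table: pd.DataFrame
    n_missing: int = 0

    def global_summary(self) -> pd.DataFrame:
        """Global totals: rows = the six quantities, columns with_trade /
        no_trade / net.  The per-fetus row is the births-weighted mean."""
        t = self.table.dropna(subset=["iq_total_wt"])
        births = t["births"]
        out = pd.DataFrame(
            index=list(TABLE1_ROWS), columns=["with_trade", "no_trade", "net"], dtype=float
        )
        for col, tag in (("with_trade", "wt"), ("no_trade", "nt"), ("net", "net")):
            out.loc["iq_per_fetus", col] = float(
                (t[f"iq_per_fetus_{tag}"] * births).sum() / births.sum()
            )
            for q in ("iq_total", "fha_deaths", "loss_iq", "loss_fha", "loss_total"):
                out.loc[q, col] = float(t[f"{q}_{tag}"].sum())
        return out


def scenario_impacts(
    e_wt: pd.Series,
    e_nt: pd.Series,
    demo: Demographics,
    params: HealthParams,
    mode: str = "per_scenario",
) -> ImpactTable:
    """Full impact chain for both scenarios, per country.

    ``mode='per_scenario'`` (default) evaluates each endpoint on each
    scenario's absolute exposure and nets the results, matching a
    per-scenario summary table; ``mode='difference'`` feeds the exposure
    difference through the dose–response once and reports it as the net
    (with-trade columns then hold the with-trade absolute impacts and the
    no-trade columns are derived as wt − net).
    """
    params.validate()
    if mode not in ("per_scenario", "difference"):
        raise ConfigurationError("mode must be 'per_scenario' or 'difference'")
    if not e_wt.index.equals(e_nt.index):
        raise ValidationError("scenario exposure tables are not aligned")
    countries = e_wt.index
    d = demo.table.reindex(countries)
    missing = d["births"].isna() | d["pop_male"].isna() | d["pop_female"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning(
            "%d countries lack demographics and are excluded from global sums: %s",
            n_missing,
            list(countries[missing]),
        )

    out = pd.DataFrame(index=countries)
    out["births"] = d["births"]
    gdp = d["gdp_pc"] if "gdp_pc" in d else None

    def chain(exposure: pd.Series) -> dict[str, pd.Series]:
        iq_pf = pd.Series(iq_decrement(exposure.values, params), index=countries)
        iq_tot = iq_pf * d["births"]
        deaths = fha_deaths(exposure, d, params)
        losses = economic_loss(iq_tot, deaths, params, gdp)
        return {
            "iq_per_fetus": iq_pf,
            "iq_total": iq_tot,
            "fha_deaths": deaths,
            "loss_iq": pd.Series(losses["loss_iq"], index=countries),
            "loss_fha": pd.Series(losses["loss_fha"], index=countries),
            "loss_total": pd.Series(losses["loss_total"], index=countries),
        }

    wt = chain(e_wt)
    if mode == "per_scenario":
        nt = chain(e_nt)
        for q in TABLE1_ROWS:
            out[f"{q}_wt"] = wt[q]
            out[f"{q}_nt"] = nt[q]
            out[f"{q}_net"] = wt[q] - nt[q]
    else:
        # the difference chain is linear for IQ but not FHA; feed |ΔE| once,
        # restore the sign, report that as the net and derive the no-trade
        # column from it
        delta = e_wt - e_nt
        sign = np.sign(delta.values)
        dchain = chain(delta.abs())
        for q in TABLE1_ROWS:
            signed = dchain[q] * sign
            out[f"{q}_wt"] = wt[q]
            out[f"{q}_net"] = signed
            out[f"{q}_nt"] = wt[q] - signed
    out.loc[missing, [c for c in out.columns if c != "births"]] = np.nan
    return ImpactTable(table=out, n_missing=n_missing)
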