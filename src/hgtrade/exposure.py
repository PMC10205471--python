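"""Per-country dietary methylmercury exposure under both scenarios.

With-trade exposure is the intake-weighted sum over three food pathways,

    ``E_WT = I_seafood·C_seafood + I_fwfish·C_fwfish + I_rice·C_rice``  (µg/day),

and the no-trade exposure rescales each pathway by the scenario ratio of its
environmental proxy — catch-weighted marine plankton MeHg for seafood,
population-weighted atmospheric deposition for freshwater fish, mean soil Hg
for rice:

    ``E_NT = (P_NT/P_WT)·I_sf·C_sf + (D_NT/D_WT)·I_fw·C_fw + (S_NT/S_WT)·I_r·C_r``.

Food consumption patterns are held fixed across scenarios; only the
environment changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ScalingError, ValidationError, WeightingError
from .grids import CountryMask, GriddedField

PATHWAYS = ("seafood", "fwfish", "rice")
#: proxy field feeding each pathway's scenario ratio
PATHWAY_PROXY = {"seafood": "P", "fwfish": "D", "rice": "S"}


def population_weighted_deposition(
    D: GriddedField, mask: CountryMask, population: GriddedField
) -> pd.Series:
    """Population-weighted mean deposition within each country's boundary."""
    D.require_same_grid(population)
    out = {}
    for code in mask.countries:
        w = mask.weights[code] * population.values
        total = float(w.sum())
        if total <= 0:
            raise WeightingError(f"country {code!r} has zero population under its mask")
        out[code] = float((D.values * w).sum() / total)
    return pd.Series(out, name="D").rename_axis("region")

def catch_weighted_plankton(
    P: GriddedField, fishcatch: dict[str, np.ndarray], countries: list[str]
) -> pd.Series:
    """Plankton MeHg weighted by each country's fish-catch distribution.

    Countries absent from ``fishcatch`` have no marine catch and come back
    as missing (NaN), never as zero; a country present with all-zero weights
    is a data error.
    """
    out = {}
    for code in countries:
        if code not in fishcatch:
            out[code] = np.nan
            continue
        w = np.asarray(fishcatch[code], dtype=float)
        if w.shape != P.shape:
            raise ValidationError(f"fish-catch weights for {code!r} do not match the grid")
        total = float(w.sum())
        if total <= 0:
            raise WeightingError(f"fish-catch weights for {code!r} sum to zero")
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"fish-catch weights for {code!r} must sum to 1")
        out[code] = float((P.values * w).sum())
    return pd.Series(out, name="P").rename_axis("region")


def mean_soil(S: GriddedField, mask: CountryMask) -> pd.Series:
    """Mask-weighted mean soil Hg concentration per country."""
    out = {}
    for code in mask.countries:
        w = mask.weights[code]
        total = float(w.sum())
        if total <= 0:
            raise WeightingError(f"country {code!r} has an empty mask")
        out[code] = float((S.values * w).sum() / total)
    return pd.Series(out, name="S").rename_axis("region")


def _check_nonneg(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        if (df[c] < 0).any():
            raise ValidationError(f"column {c!r} has negative entries")


def pathway_exposures(diets: pd.DataFrame, conc: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway with-trade exposure ``I·C`` (µg/day), one column per
    pathway."""
    _check_nonneg(diets, [f"I_{p}" for p in PATHWAYS])
    _check_nonneg(conc, [f"C_{p}" for p in PATHWAYS])
    out = pd.DataFrame(index=diets.index)
    for p in PATHWAYS:
        out[p] = diets[f"I_{p}"] * conc[f"C_{p}"]
    return out


def exposure_with_trade(diets: pd.DataFrame, conc: pd.DataFrame) -> pd.Series:
    """Total with-trade MeHg exposure per country (µg/day)."""
    return pathway_exposures(diets, conc).sum(axis=1).rename("E_WT")


def scenario_ratios(env: pd.DataFrame) -> pd.DataFrame:
    """No-trade / with-trade proxy ratio per pathway from a table with
    columns ``{P,D,S}_{WT,NT}``."""
    out = pd.DataFrame(index=env.index)
    for p, proxy in PATHWAY_PROXY.items():
        out[p] = env[f"{proxy}_NT"] / env[f"{proxy}_WT"]
    return out


def exposure_no_trade(
    diets: pd.DataFrame, conc: pd.DataFrame, env: pd.DataFrame
) -> pd.Series:
    """Total no-trade exposure, rescaling each consumed pathway by its proxy
    ratio.  Pathways with zero intake are skipped outright (no 0/0); a zero
    or missing with-trade proxy under positive intake is an error."""
    wt = pathway_exposures(diets, conc)
    total = pd.Series(0.0, index=wt.index, name="E_NT")
    for p, proxy in PATHWAY_PROXY.items():
        intake = wt[p]
        active = intake > 0
        wt_proxy = env.loc[active, f"{proxy}_WT"]
        bad = wt_proxy.isna() | (wt_proxy <= 0)
        if bad.any():
            raise ScalingError(
                f"with-trade proxy {proxy!r} missing or nonpositive for "
                f"{list(wt_proxy.index[bad])} with positive {p} intake"
            )
        ratio = env[f"{proxy}_NT"] / env[f"{proxy}_WT"]
        total[active] += intake[active] * ratio[active]
    return total


def no_trade_pathways(
    diets: pd.DataFrame, conc: pd.DataFrame, env: pd.DataFrame
) -> pd.DataFrame:
    """Per-pathway no-trade exposures (same skipping rules as the total)."""
    wt = pathway_exposures(diets, conc)
    out = pd.DataFrame(0.0, index=wt.index, columns=list(PATHWAYS))
    for p, proxy in PATHWAY_PROXY.items():
        active = wt[p] > 0
        ratio = env[f"{proxy}_NT"] / env[f"{proxy}_WT"]
        out.loc[active, p] = wt.loc[active, p] * ratio[active]
    return out


def exposure_delta_decomposition(
    wt_pathways: pd.DataFrame, nt_pathways: pd.DataFrame
) -> pd.DataFrame:
    """Per-pathway contribution to ΔE = E_NT − E_WT (the exposure a country
    would face without trade, positive where trade is protective); pathway
    columns sum exactly to the ``total`` column."""
    if list(wt_pathways.columns) != list(nt_pathways.columns) or not wt_pathways.index.equals(
        nt_pathways.index
    ):
        raise ValidationError("pathway tables are not aligned")
    delta = nt_pathways - wt_pathways
    delta["total"] = delta[list(PATHWAYS)].sum(axis=1)
    return delta


def country_environment(
    fields_wt, fields_nt, mask: CountryMask, population: GriddedField,
    fishcatch: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Assemble the per-country proxy table (columns ``{P,D,S}_{WT,NT}``)
    from two scenarios' environmental fields."""
    countries = mask.countries
    env = pd.DataFrame(index=pd.Index(countries, name="region"))
    for tag, f in (("WT", fields_wt), ("NT", fields_nt)):
        env[f"D_{tag}"] = population_weighted_deposition(f.D, mask, population)
        env[f"P_{tag}"] = catch_weighted_plankton(f.P, fishcatch, countries)
        env[f"S_{tag}"] = mean_soil(f.S, mask)
    return env
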