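"""The counterfactual "no trade" gridded emission inventory.

Under autarky each country would produce domestically what it now imports,
at the exporter's emission level, so its emissions become its
consumption-based total while the *spatial pattern* of its production stays
fixed: within a country's masked cells the with-trade inventory is rescaled
by ``cba_c / pba_c``.  Cells outside every mask are untouched, and because
Σ PBA = Σ CBA the global total is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AllocationError, ValidationError
from .grids import CountryMask, GriddedField

logger = logging.getLogger(__name__)


@dataclass
class ScenarioPair:
    """With-trade and no-trade inventories with equal global totals."""

    with_trade: GriddedField
    no_trade: GriddedField

    def __post_init__(self) -> None:
        self.with_trade.require_same_grid(self.no_trade)
        a, b = self.with_trade.global_sum(), self.no_trade.global_sum()
        if abs(a - b) > 1e-6 * max(abs(a), 1e-300):
            raise ValidationError(
                f"global totals differ between scenarios: {a:.6g} vs {b:.6g}"
            )


def no_trade_inventory(
    with_trade: GriddedField,
    mask: CountryMask,
    pba_totals: pd.Series,
    cba_totals: pd.Series,
) -> ScenarioPair:
    """Rescale each country's masked emissions from PBA to CBA totals.

    Preconditions: masked grid sums agree with ``pba_totals`` to 1e-4
    relative, CBA is nonnegative, and global PBA equals global CBA to 1e-6
    relative.  A country with zero production but positive consumption has no
    spatial pattern to scale; its CBA is spread uniformly over its masked
    cells (mask-weighted) with a logged warning.
    """
    if with_trade.values.shape != (mask.lat.size, mask.lon.size):
        raise ValidationError("inventory grid does not match the country mask grid")
    countries = mask.countries
    missing = set(countries) - set(pba_totals.index) | set(countries) - set(cba_totals.index)
    if missing:
        raise ValidationError(f"totals missing for countries {sorted(missing)}")
    if np.any(cba_totals.loc[countries] < 0):
        raise ValidationError("cba totals must be nonnegative")
    tot_p = float(pba_totals.loc[countries].sum())
    tot_c = float(cba_totals.loc[countries].sum())
    if abs(tot_p - tot_c) > 1e-6 * max(abs(tot_p), 1e-300):
        raise ValidationError(
            f"global PBA ({tot_p:.6g}) and CBA ({tot_c:.6g}) totals differ"
        )

    values = with_trade.values.copy()
    for code in countries:
        w = mask.weights[code]
        masked_sum = float((with_trade.values * w).sum())
        pba_c = float(pba_totals[code])
        cba_c = float(cba_totals[code])
        if abs(masked_sum - pba_c) > 1e-4 * max(abs(pba_c), 1e-300):
            raise ValidationError(
                f"masked grid sum for {code!r} ({masked_sum:.6g}) inconsistent "
                f"with pba total ({pba_c:.6g})"
            )
        if pba_c == 0:
            if cba_c == 0:
                continue
            w_sum = float(w.sum())
            if w_sum == 0:
                raise AllocationError(
                    f"country {code!r} consumes {cba_c:.3g} Mg/yr but has neither "
                    "production pattern nor masked cells to allocate it to"
                )
            logger.warning(
                "country %s has zero production; distributing %.3g Mg/yr "
                "uniformly over its %d masked cells",
                code,
                cba_c,
                int((w > 0).sum()),
            )
            values += w * (cba_c / w_sum)
            continue
        # replace the country's owned share of each cell with the rescaled one
        values += w * with_trade.values * (cba_c / pba_c - 1.0)

    no_trade = with_trade.copy_with(values)
    return ScenarioPair(with_trade=with_trade, no_trade=no_trade)


def scenario_delta(pair: ScenarioPair) -> GriddedField:
    """Per-cell with-trade minus no-trade emissions; sums to ~0 globally."""
    pair.with_trade.require_same_grid(pair.no_trade)
    return pair.with_trade.copy_with(pair.with_trade.values - pair.no_trade.values)
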