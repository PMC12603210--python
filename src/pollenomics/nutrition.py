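"""Food-security indicators: per-capita nutrient availability.

Consumption quantities are converted into daily per-capita availability of
energy (kcal), vitamin A and folate using exogenous nutrient coefficients
per product ton, then compared between a baseline and a shocked market state
by crop group and region bloc.  "Availability" is supply reaching consumers,
not intake net of waste.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import require_columns
from .market import CalibratedModel, EquilibriumState

NUTRIENTS = ("kcal", "vitA", "folate")


def nutrient_availability(
    consumption: pd.Series,
    coefficients: pd.DataFrame,
    population: float,
) -> dict[str, float]:
    """Per-capita daily availability of each nutrient.

    ``consumption`` maps commodity_id -> tons/year; coefficients carry
    ``commodity_id, kcal_per_ton, vitA_per_ton, folate_per_ton``.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    require_columns(coefficients, ["commodity_id"] + [f"{n}_per_ton" for n in NUTRIENTS], "coefficients")
    coeff = coefficients.set_index("commodity_id")
    consumed = consumption[consumption > 0] if len(consumption) else consumption
    missing = set(consumed.index) - set(coeff.index)
    if missing:
        raise ValueError(f"no nutrient coefficients for consumed commodities: {sorted(missing)}")
    out = {}
    for nut in NUTRIENTS:
        per_ton = coeff[f"{nut}_per_ton"].reindex(consumption.index).fillna(0.0)
        out[nut] = float((consumption * per_ton).sum() / population / 365.0)
    return out


def nutrition_change_report(
    model: CalibratedModel,
    state: EquilibriumState,
    coefficients: pd.DataFrame,
    commodity_groups: pd.DataFrame,
    blocs: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Percent change in nutrient availability by bloc and crop group.

    ``commodity_groups`` carries ``commodity_id, group``; every report also
    includes an ``all_food`` row aggregating every commodity.  Population
    cancels in the percent change, so blocs sum quantities directly.
    """
    require_columns(commodity_groups, ["commodity_id", "group"], "commodity_groups")
    coeff = coefficients.set_index("commodity_id")
    missing = set(model.commodity_ids) - set(coeff.index)
    if missing:
        raise ValueError(f"no nutrient coefficients for commodities: {sorted(missing)}")
    groups = {"all_food": list(model.commodity_ids)}
    for g, sub in commodity_groups.groupby("group"):
        groups[str(g)] = list(sub["commodity_id"])
    cidx = {k: i for i, k in enumerate(model.commodity_ids)}
    b = model.baseline
    rows = []
    for bloc_name, mask in blocs.items():
        mask = np.asarray(mask, bool)
        q0 = b.demand[mask].sum(axis=0)       # baseline consumption by commodity
        q1 = state.demand[mask].sum(axis=0)
        for group_name, members in groups.items():
            js = [cidx[m] for m in members if m in cidx]
            if not js:
                raise ValueError(f"commodity group '{group_name}' is empty")
            row = {"bloc": bloc_name, "group": group_name}
            for nut in NUTRIENTS:
                kappa = coeff[f"{nut}_per_ton"].reindex(model.commodity_ids).to_numpy(float)
                base = float((q0[js] * kappa[js]).sum())
                new = float((q1[js] * kappa[js]).sum())
                row[f"pct_change_{nut}"] = 100.0 * (new / base - 1.0) if base > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
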