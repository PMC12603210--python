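"""Welfare decomposition and back-of-envelope valuation calculators.

Welfare changes are decomposed into three money-metric components per region:

* consumer surplus — the Marshallian integral of the calibrated composite
  demand curve between base and scenario consumer price indices (with no
  income effects in a partial-equilibrium demand curve this coincides with
  the compensating-income measure);
* producer surplus — the change in the area between price and the calibrated
  constant-elasticity supply curve, ``PS = p*Q / (1 + eps_s)``;
* government revenue — ad-valorem wedge receipts on import flows.

The total is the exact component sum, so adding-up holds to machine
precision at every aggregation level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._util import round_half_up
from .market import CalibratedModel, EquilibriumState


def consumer_surplus_change(eps_d, base_demand, p0, p1):
    """Marshallian consumer-surplus change for a constant-elasticity demand.

    ``-integral_{p0}^{p1} D(p) dp`` with ``D(p) = base_demand * (p/p0)^eps_d``;
    negative when the price rises.  The unit-elastic case uses the log form.
    """
    eps = np.asarray(eps_d, float)
    q0 = np.asarray(base_demand, float)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if (p0 <= 0).any() if p0.ndim else p0 <= 0:
        raise ValueError("prices must be strictly positive")
    ratio = p1 / p0
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = -q0 * p0 * (ratio ** (eps + 1.0) - 1.0) / np.where(eps == -1.0, 1.0, eps + 1.0)
        log_form = -q0 * p0 * np.log(ratio)
    return np.where(eps == -1.0, log_form, generic)


def producer_surplus_change(model: CalibratedModel, state: EquilibriumState) -> np.ndarray:
    """Per-(region, commodity) producer-surplus change vs. the baseline.

    For supply ``Q = k p^eps_s`` the surplus over variable cost is
    ``p*Q/(1+eps_s)``; the change is evaluated at scenario and base
    price/quantity pairs of the calibrated curves.
    """
    b = model.baseline
    ps1 = state.producer_price * state.supply / (1.0 + b.eps_s)
    ps0 = b.producer_price * b.production / (1.0 + b.eps_s)
    return ps1 - ps0


def government_revenue_change(model: CalibratedModel, state: EquilibriumState) -> np.ndarray:
    """Change in ad-valorem wedge receipts by destination region."""
    b = model.baseline
    rev1 = (state.flows * state.producer_price[:, None, :] * b.tau).sum(axis=(0, 2))
    rev0 = (b.flows * b.producer_price[:, None, :] * b.tau).sum(axis=(0, 2))
    return rev1 - rev0


def baseline_tariff_revenue(model: CalibratedModel) -> np.ndarray:
    b = model.baseline
    return (b.flows * b.producer_price[:, None, :] * b.tau).sum(axis=(0, 2))


@dataclasses.dataclass(frozen=True)
class WelfareAccount:
    region_id: str
    delta_cs: float
    delta_ps: float
    delta_gov: float
    total: float
    share_of_baseline_welfare: float
    share_of_gdp: float


def welfare_accounts(model: CalibratedModel, state: EquilibriumState) -> pd.DataFrame:
    """Regional welfare decomposition table.

    ``share_of_baseline_welfare`` normalizes by a baseline agri-food sector
    denominator (consumer expenditure + producer surplus + tariff revenue);
    the unbounded Marshallian CS level of an inelastic constant-elasticity
    demand rules out a literal baseline CS level.
    """
    b = model.baseline
    d_cs = consumer_surplus_change(
        b.eps_d, b.demand, b.consumer_price, state.consumer_price
    ).sum(axis=1)
    d_ps = producer_surplus_change(model, state).sum(axis=1)
    d_gov = government_revenue_change(model, state)
    total = d_cs + d_ps + d_gov
    base_exp = (b.demand * b.consumer_price).sum(axis=1)
    base_ps = (b.producer_price * b.production / (1.0 + b.eps_s)).sum(axis=1)
    denom = base_exp + base_ps + baseline_tariff_revenue(model)
    return pd.DataFrame({
        "region_id": model.region_ids,
        "delta_cs": d_cs,
        "delta_ps": d_ps,
        "delta_gov": d_gov,
        "total": total,
        "share_of_baseline_welfare": total / denom,
        "share_of_gdp": total / b.gdp,
    })


def aggregate_welfare(accounts: pd.DataFrame, blocs: dict[str, set[str]],
                      gdp: pd.Series | None = None) -> pd.DataFrame:
    """Component-wise bloc sums; blocs inside one call must not overlap."""
    seen: set[str] = set()
    for name, members in blocs.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"overlapping blocs in one aggregation (bloc '{name}'): {sorted(overlap)}")
        seen |= set(members)
    rows = []
    for name, members in blocs.items():
        sub = accounts[accounts["region_id"].isin(members)]
        row = {
            "bloc": name,
            "delta_cs": sub["delta_cs"].sum(),
            "delta_ps": sub["delta_ps"].sum(),
            "delta_gov": sub["delta_gov"].sum(),
        }
        row["total"] = row["delta_cs"] + row["delta_ps"] + row["delta_gov"]
        if gdp is not None:
            row["share_of_gdp"] = row["total"] / gdp.loc[gdp.index.isin(members)].sum()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# back-of-envelope valuation arithmetic
# ---------------------------------------------------------------------------

def wtp_extrapolation(wtp_per_household: float, households: float) -> float:
    """Annual willingness-to-pay scaled to a household population (EUR/year)."""
    if wtp_per_household < 0 or households < 0:
        raise ValueError("inputs must be non-negative")
    return wtp_per_household * households


def wtp_billions(wtp_per_household: float, households: float) -> float:
    """WTP extrapolation reported in billions, one decimal, half-up."""
    return round_half_up(wtp_extrapolation(wtp_per_household, households) / 1e9, 1)


def replacement_cost(
    colonies_added: float,
    cost_per_colony_low: float,
    cost_per_colony_high: float,
    dependent_area: float | None = None,
) -> dict[str, float]:
    """Cost range of substituting the lost service with managed colonies.

    Returns total low/high (EUR/year) and, when ``dependent_area`` (ha) is
    given, the per-hectare range.
    """
    if min(colonies_added, cost_per_colony_low, cost_per_colony_high) < 0:
        raise ValueError("inputs must be non-negative")
    out = {
        "total_low": colonies_added * cost_per_colony_low,
        "total_high": colonies_added * cost_per_colony_high,
    }
    if dependent_area is not None:
        if dependent_area <= 0:
            raise ValueError("dependent_area must be positive for per-hectare output")
        out["per_ha_low"] = out["total_low"] / dependent_area
        out["per_ha_high"] = out["total_high"] / dependent_area
    return out


def relative_change(reference_value: float, alternative_value: float) -> float:
    """How much lower the alternative is than the reference, in percent
    (one decimal, half-up)."""
    if reference_value == 0:
        raise ValueError("reference value must be non-zero")
    return round_half_up(100.0 * (reference_value - alternative_value) / reference_value, 1)
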