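"""Experiment designs: confidence-interval scenarios, the full-factorial
sensitivity grid, dependence-source comparison, and the descriptive
voting-behavior association.

A "scenario" is one end-to-end pipeline pass: dependence tables -> shock
table -> calibrated market model -> equilibrium -> welfare and nutrition
indicators.  The sensitivity grid reruns that pass under a full factorial of
multiplicative parameter levels (default 4 factors x 3 levels = 81 runs).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .market import (
    BaselineMarket,
    CalibratedModel,
    EquilibriumState,
    calibrate_baseline,
    solve_equilibrium,
)
from .nutrition import nutrition_change_report
from .shock import build_shock_table, map_crops_to_commodities
from .welfare import relative_change, welfare_accounts

SHOCK_LEVELS = ("low", "mean", "high")

FACTOR_NAMES = ("wild_contribution", "dependence_ratio", "supply_elasticity", "trade_elasticity")


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One pipeline configuration: which shock column, which dependence data."""

    shock_level: str = "mean"
    dependence_source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.shock_level not in SHOCK_LEVELS:
            raise ValueError(f"shock_level must be one of {SHOCK_LEVELS}")


@dataclasses.dataclass(frozen=True)
class SensitivityFactor:
    """A named parameter dimension with exactly three multiplicative levels."""

    name: str
    levels: tuple[float, float, float] = (0.5, 1.0, 1.5)

    def __post_init__(self) -> None:
        if self.name not in FACTOR_NAMES:
            raise ValueError(f"unknown factor '{self.name}'; expected one of {FACTOR_NAMES}")
        if len(self.levels) != 3:
            raise ValueError("each sensitivity factor needs exactly 3 levels")
        if self.levels[1] != 1.0:
            raise ValueError("the central level must be 1.0 (the core scenario)")


def default_factors() -> list[SensitivityFactor]:
    return [SensitivityFactor(name) for name in FACTOR_NAMES]


# ---------------------------------------------------------------------------
# pipeline building blocks
# ---------------------------------------------------------------------------

def _scaled_dependence(dep: pd.DataFrame, scale: float) -> pd.DataFrame:
    out = dep.copy()
    for col in ("D_mean", "D_min", "D_max"):
        if col in out.columns:
            out[col] = np.clip(out[col] * scale, 0.0, 1.0)
    return out


def build_shocks(
    dataset,
    dependence: pd.DataFrame | None = None,
    phi_scale: float = 1.0,
    dependence_scale: float = 1.0,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Shock table for a dataset, optionally swapping or scaling inputs.

    Scaling factors above one are clipped so ratios and contributions stay in
    [0, 1]; the min <= mean <= max ordering survives the monotone clip.
    """
    dep = dataset.dependence if dependence is None else dependence
    dep = _scaled_dependence(dep, dependence_scale)
    phi = dataset.wild_contribution.copy()
    phi["phi"] = np.clip(phi["phi"] * phi_scale, 0.0, 1.0)
    shares = map_crops_to_commodities(dataset.production_values)
    return build_shock_table(
        dep, phi, shares,
        europe_regions=dataset.europe_regions,
        all_regions=dataset.all_regions,
        coverage=coverage,
    )


def build_model(
    dataset,
    supply_scale: float = 1.0,
    trade_scale: float = 1.0,
) -> CalibratedModel:
    """Calibrated market model, optionally scaling supply/trade elasticities."""
    baseline = BaselineMarket.from_dataset(dataset)
    baseline.eps_s = baseline.eps_s * supply_scale
    baseline.sigma1 = baseline.sigma1 * trade_scale
    baseline.sigma2 = baseline.sigma2 * trade_scale
    return calibrate_baseline(baseline)


def standard_blocs(model: CalibratedModel) -> dict[str, np.ndarray]:
    b = model.baseline
    return {
        "eu": b.in_eu,
        "europe": b.in_europe,
        "extra_europe": ~b.in_europe,
        "world": np.ones_like(b.in_europe, dtype=bool),
    }


def headline_indicators(
    model: CalibratedModel,
    state: EquilibriumState,
    dataset,
) -> dict[str, float]:
    """The indicator set tracked across scenarios and sensitivity runs.

    Per bloc (EU / Europe / extra-Europe / world): total welfare change and
    its consumer-surplus part (EUR), vitamin A availability change (%), and
    value-weighted production and producer-price changes of
    pollination-dependent commodities (%).
    """
    b = model.baseline
    accounts = welfare_accounts(model, state)
    blocs = standard_blocs(model)
    dep_mask = dataset.commodities.set_index("commodity_id")["pollination_dependent"]
    js = [j for j, com in enumerate(model.commodity_ids) if dep_mask.get(com, False)]
    nutrition = nutrition_change_report(
        model, state, dataset.nutrients,
        dataset.commodities[["commodity_id", "group"]], blocs,
    )
    out: dict[str, float] = {}
    region_index = pd.Index(model.region_ids)
    for name, mask in blocs.items():
        members = set(region_index[mask])
        sub = accounts[accounts["region_id"].isin(members)]
        out[f"welfare_total_{name}"] = float(sub["total"].sum())
        out[f"welfare_cs_{name}"] = float(sub["delta_cs"].sum())
        w = (b.production * b.producer_price)[np.ix_(mask, js)]
        w = w / w.sum()
        prod_rel = state.supply[np.ix_(mask, js)] / b.production[np.ix_(mask, js)] - 1.0
        price_rel = state.producer_price[np.ix_(mask, js)] / b.producer_price[np.ix_(mask, js)] - 1.0
        out[f"production_dependent_pct_{name}"] = float((w * prod_rel).sum() * 100.0)
        out[f"producer_price_dependent_pct_{name}"] = float((w * price_rel).sum() * 100.0)
        row = nutrition[(nutrition["bloc"] == name) & (nutrition["group"] == "all_food")]
        out[f"vitA_all_food_pct_{name}"] = float(row["pct_change_vitA"].iloc[0])
    return out


def run_scenario(
    dataset,
    shock_table: pd.DataFrame,
    level: str = "mean",
    model: CalibratedModel | None = None,
    **solver_kwargs,
) -> tuple[CalibratedModel, EquilibriumState, dict[str, float]]:
    """Solve one scenario and return (model, state, indicators)."""
    if level not in SHOCK_LEVELS:
        raise ValueError(f"level must be one of {SHOCK_LEVELS}")
    if model is None:
        model = build_model(dataset)
    state = solve_equilibrium(model, shocks=shock_table, shock_column=f"s_{level}", **solver_kwargs)
    return model, state, headline_indicators(model, state, dataset)


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

def run_ci_scenarios(
    dataset,
    shock_table: pd.DataFrame,
    model: CalibratedModel | None = None,
    **solver_kwargs,
) -> dict:
    """Solve the low / mean / high shock scenarios and envelope the results.

    Any non-converged member raises, failing the whole run.  Returns the
    three indicator dicts plus a per-indicator (min, core, max) envelope.
    """
    if model is None:
        model = build_model(dataset)
    results = {}
    for level in SHOCK_LEVELS:
        _, state, indicators = run_scenario(
            dataset, shock_table, level=level, model=model, **solver_kwargs
        )
        results[level] = {"state": state, "indicators": indicators}
    names = list(results["mean"]["indicators"])
    envelope = pd.DataFrame({
        "indicator": names,
        "low": [results["low"]["indicators"][k] for k in names],
        "mean": [results["mean"]["indicators"][k] for k in names],
        "high": [results["high"]["indicators"][k] for k in names],
    })
    envelope["env_min"] = envelope[["low", "mean", "high"]].min(axis=1)
    envelope["env_max"] = envelope[["low", "mean", "high"]].max(axis=1)
    results["envelope"] = envelope
    return results


def run_sensitivity_grid(
    dataset,
    factors: list[SensitivityFactor] | None = None,
    coverage: float = 0.95,
    **solver_kwargs,
) -> dict:
    """Full-factorial sensitivity experiment (3^k runs).

    Each run rescales the factor's central values multiplicatively, rebuilds
    the shocks and the calibrated model, and solves the mean-shock scenario.
    Returns the long results table, per-indicator summary statistics
    (median, IQR, min, max) and the core (all-central) run.
    """
    if factors is None:
        factors = default_factors()
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names: {names}")
    records = []
    core_key = tuple(1.0 for _ in factors)
    runs: dict[tuple, dict[str, float]] = {}
    for combo in itertools.product(*[f.levels for f in factors]):
        levels = dict(zip(names, combo))
        shocks = build_shocks(
            dataset,
            phi_scale=levels.get("wild_contribution", 1.0),
            dependence_scale=levels.get("dependence_ratio", 1.0),
            coverage=coverage,
        )
        model = build_model(
            dataset,
            supply_scale=levels.get("supply_elasticity", 1.0),
            trade_scale=levels.get("trade_elasticity", 1.0),
        )
        _, _, indicators = run_scenario(dataset, shocks, level="mean", model=model, **solver_kwargs)
        runs[combo] = indicators
        for ind, val in indicators.items():
            records.append({**levels, "indicator": ind, "value": val})
    table = pd.DataFrame(records)
    summary = (
        table.groupby("indicator")["value"]
        .agg(
            median="median",
            iqr=lambda v: float(v.quantile(0.75) - v.quantile(0.25)),
            min="min",
            max="max",
        )
        .reset_index()
    )
    return {
        "table": table,
        "summary": summary,
        "runs": runs,
        "core": runs[core_key],
        "n_runs": len(runs),
    }


def compare_dependence_sources(
    dataset,
    source_a: pd.DataFrame,
    source_b: pd.DataFrame,
    welfare_indicator: str = "welfare_total_world",
    **solver_kwargs,
) -> dict:
    """Identical pipeline under two dependence-ratio vintages.

    Returns both indicator sets, the per-commodity mean-shock deltas and the
    relative change of the headline welfare loss (positive = source_b gives
    a smaller loss).
    """
    crops_a, crops_b = set(source_a["crop_id"]), set(source_b["crop_id"])
    if crops_a != crops_b:
        raise ValueError(
            "dependence sources cover different crops: "
            f"only-in-a={sorted(crops_a - crops_b)}, only-in-b={sorted(crops_b - crops_a)}"
        )
    model = build_model(dataset)
    out = {}
    shocks = {}
    for tag, source in (("a", source_a), ("b", source_b)):
        shock_table = build_shocks(dataset, dependence=source)
        _, _, indicators = run_scenario(
            dataset, shock_table, level="mean", model=model, **solver_kwargs
        )
        out[tag] = indicators
        shocks[tag] = shock_table
    delta = shocks["a"][["region_id", "commodity_id", "s_mean"]].merge(
        shocks["b"][["region_id", "commodity_id", "s_mean"]],
        on=["region_id", "commodity_id"],
        suffixes=("_a", "_b"),
    )
    delta["shock_delta"] = delta["s_mean_b"] - delta["s_mean_a"]
    loss_a = -out["a"][welfare_indicator]
    loss_b = -out["b"][welfare_indicator]
    return {
        "indicators_a": out["a"],
        "indicators_b": out["b"],
        "shock_deltas": delta,
        "welfare_loss_a": loss_a,
        "welfare_loss_b": loss_b,
        "relative_change_pct": relative_change(loss_a, loss_b),
    }


# ---------------------------------------------------------------------------
# voting-behavior association (descriptive, not causal)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AssociationResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> AssociationResult:
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    return AssociationResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(y),
    )


def vote_association(
    votes: pd.DataFrame,
    welfare_share_of_gdp: pd.Series,
) -> dict[str, AssociationResult]:
    """Population-weighted regression of parliamentary rejection shares on
    consumer-welfare change (share of GDP), per proposal and for their
    average.  Descriptive only; no causal claim.
    """
    merged = votes.merge(
        welfare_share_of_gdp.rename("welfare_share").rename_axis("member_state").reset_index(),
        on="member_state",
        how="inner",
    )
    if len(merged) < 3:
        raise ValueError(f"need at least 3 matched member states, got {len(merged)}")
    if (merged["population"] <= 0).any():
        raise ValueError("population weights must be strictly positive")
    x = merged["welfare_share"].to_numpy(float)
    w = merged["population"].to_numpy(float)
    out = {
        "nrl": _wls(merged["rejection_share_nrl"].to_numpy(float), x, w),
        "sur": _wls(merged["rejection_share_sur"].to_numpy(float), x, w),
    }
    avg = (merged["rejection_share_nrl"] + merged["rejection_share_sur"]).to_numpy(float) / 2.0
    out["avg"] = _wls(avg, x, w)
    return out
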