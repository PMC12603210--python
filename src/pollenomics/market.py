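"""Stylized multi-region partial-equilibrium model of agri-food markets.

The model clears one world market per commodity, with each region's good
treated as an imperfect substitute for the others (Armington).  Functional
forms are constant-elasticity throughout, written in "calibrated share" form
so the observed base year is an exact equilibrium by construction:

* supply        ``Q = Q0 * m * (p/p0)^eps_s * Rbar^lam``
* realized yield``y = y0 * m * (p/p0)^eta``        (price-driven intensification)
* area          ``A = Q / y = A0 * (p/p0)^(eps_s - eta) * Rbar^lam``
* demand        ``X = X0 * (Pc/Pc0)^eps_d``        (composite consumer price)
* allocation    two-level CES: domestic vs. import composite (sigma1), then
  across origins (sigma2), with baseline value shares as CES weights
* price links   landed price = origin price * (1 + tau); the ad-valorem wedge
  accrues to the destination government

``m = 1 - s`` is the exogenous yield multiplier from the pollinator shock and
``Rbar`` a region's area-weighted per-hectare return index (equal to 1 in the
base year), whose elasticity ``lam`` governs total cropland expansion.

Equilibrium producer prices are found by a damped diagonal quasi-Newton
tatonnement on log prices; with constant elasticities this converges
geometrically for any empirically sensible parameter set.  The solve is pure
deterministic NumPy: identical inputs give bit-identical states.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


class ConvergenceError(RuntimeError):
    """Solver failed to clear markets; carries the residual trajectory."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# baseline container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BaselineMarket:
    """Observed base-year market state on dense [region, commodity] arrays."""

    region_ids: list[str]
    commodity_ids: list[str]
    in_europe: np.ndarray        # (n,) bool
    in_eu: np.ndarray            # (n,) bool
    production: np.ndarray       # (n, c) kt
    demand: np.ndarray           # (n, c) kt, composite consumption
    producer_price: np.ndarray   # (n, c) EUR/t
    consumer_price: np.ndarray   # (n, c) EUR/t, composite unit expenditure
    area: np.ndarray             # (n, c) ha
    flows: np.ndarray            # (o, d, c) kt bilateral trade, diagonal 0
    tau: np.ndarray              # (o, d, c) ad-valorem wedge
    eps_s: np.ndarray            # (n, c) > 0
    eps_d: np.ndarray            # (n, c) < 0
    eta: np.ndarray              # (n, c) >= 0
    sigma1: np.ndarray           # (n, c) > 0, domestic vs import nest
    sigma2: np.ndarray           # (n, c) > 0, across origins
    land_elasticity: np.ndarray  # (n,)
    gdp: np.ndarray              # (n,)
    population: np.ndarray      # (n,)
    households: np.ndarray      # (n,)

    @classmethod
    def from_dataset(cls, ds) -> "BaselineMarket":
        """Assemble dense arrays from a :class:`~pollenomics.synthetic.SyntheticDataset`."""
        regions = ds.regions.set_index("region_id")
        region_ids = list(regions.index)
        commodity_ids = list(ds.commodities["commodity_id"])
        n, c = len(region_ids), len(commodity_ids)
        ridx = {r: i for i, r in enumerate(region_ids)}
        cidx = {k: i for i, k in enumerate(commodity_ids)}

        def pivot(df, col):
            out = np.zeros((n, c))
            out[df["region_id"].map(ridx), df["commodity_id"].map(cidx)] = df[col]
            return out

        flows = np.zeros((n, n, c))
        t = ds.trade
        flows[t["origin"].map(ridx), t["destination"].map(ridx), t["commodity_id"].map(cidx)] = t["qty"]
        tau = np.zeros((n, n, c))
        w = ds.wedges
        tau[w["origin"].map(ridx), w["destination"].map(ridx), w["commodity_id"].map(cidx)] = w["tau"]
        e = ds.elasticities
        return cls(
            region_ids=region_ids,
            commodity_ids=commodity_ids,
            in_europe=regions["in_europe"].to_numpy(bool),
            in_eu=regions["in_eu"].to_numpy(bool),
            production=pivot(ds.market, "production_qty"),
            demand=pivot(ds.market, "demand_qty"),
            producer_price=pivot(ds.market, "producer_price"),
            consumer_price=pivot(ds.market, "consumer_price"),
            area=pivot(ds.market, "area"),
            flows=flows,
            tau=tau,
            eps_s=pivot(e, "eps_s"),
            eps_d=pivot(e, "eps_d"),
            eta=pivot(e, "eta"),
            sigma1=pivot(e, "sigma1"),
            sigma2=pivot(e, "sigma2"),
            land_elasticity=regions["land_elasticity"].to_numpy(float),
            gdp=regions["gdp"].to_numpy(float),
            population=regions["population"].to_numpy(float),
            households=regions["households"].to_numpy(float),
        )

    def validate(self, rtol: float = 1e-6) -> None:
        if (self.producer_price <= 0).any() or (self.consumer_price <= 0).any():
            raise ValueError("all baseline prices must be strictly positive")
        if (self.eps_s <= 0).any():
            raise ValueError("supply elasticities must be strictly positive")
        if (self.eps_d >= 0).any():
            raise ValueError("demand own-price elasticities must be negative")
        if (self.tau < 0).any():
            raise ValueError("price-transmission wedges must be non-negative")
        if np.diagonal(self.flows, axis1=0, axis2=1).any():
            raise ValueError("bilateral flow matrix must have a zero diagonal")
        # physical consistency: production = domestic use + exports, where
        # domestic use = demand - imports; this is the world-balance condition
        imports = self.flows.sum(axis=0)
        exports = self.flows.sum(axis=1)
        dom_use = self.demand - imports
        if (dom_use < -rtol * np.maximum(self.demand, 1.0)).any():
            raise ValueError("imports exceed demand somewhere: unbalanced baseline trade")
        imbalance = self.production - (dom_use + exports)
        scale = np.maximum(self.production, 1.0)
        rel = np.abs(imbalance) / scale
        if (rel > rtol).any():
            per_com = {
                com: float(np.abs(imbalance[:, j]).sum() / max(self.production[:, j].sum(), 1.0))
                for j, com in enumerate(self.commodity_ids)
            }
            raise ValueError(
                "baseline world trade does not balance; relative imbalance by commodity: "
                f"{per_com}"
            )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CalibratedModel:
    """Baseline plus the share/scale parameters that make it an equilibrium.

    In calibrated share form the CES weights are the base-year value shares
    and all scale constants are the base-year quantities themselves, so the
    calibration identity holds exactly by construction.
    """

    baseline: BaselineMarket
    dom_use0: np.ndarray        # (n, c)
    imports0: np.ndarray        # (n, c) by destination
    import_value_share0: np.ndarray  # (o, d, c); zero column where no imports
    dom_value_share0: np.ndarray     # (d, c) domestic share of consumer expenditure
    area_share0: np.ndarray     # (n, c) base area shares within each region
    yield0: np.ndarray          # (n, c)
    calibration_residual: float = 0.0

    @property
    def region_ids(self):
        return self.baseline.region_ids

    @property
    def commodity_ids(self):
        return self.baseline.commodity_ids


def calibrate_baseline(baseline: BaselineMarket) -> CalibratedModel:
    """Validate a baseline and derive calibrated share parameters."""
    baseline.validate()
    imports0 = baseline.flows.sum(axis=0)
    dom_use0 = np.maximum(baseline.demand - imports0, 0.0)
    landed_value = baseline.flows * baseline.producer_price[:, None, :] * (1.0 + baseline.tau)
    total_import_value = landed_value.sum(axis=0)             # (d, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        ivs = np.where(total_import_value > 0, landed_value / np.where(total_import_value > 0, total_import_value, 1.0), 0.0)
    dom_value = dom_use0 * baseline.producer_price
    total_value = dom_value + total_import_value
    dvs = np.where(total_value > 0, dom_value / np.where(total_value > 0, total_value, 1.0), 1.0)
    area_total = baseline.area.sum(axis=1, keepdims=True)
    area_share0 = baseline.area / np.where(area_total > 0, area_total, 1.0)
    yield0 = baseline.production / np.where(baseline.area > 0, baseline.area, 1.0)
    model = CalibratedModel(
        baseline=baseline,
        dom_use0=dom_use0,
        imports0=imports0,
        import_value_share0=ivs,
        dom_value_share0=dvs,
        area_share0=area_share0,
        yield0=yield0,
    )
    # calibration identity: a zero-shock solve must return the baseline
    state = solve_equilibrium(model, shock_multiplier=None)
    rel_p = np.abs(state.producer_price / baseline.producer_price - 1.0).max()
    rel_q = np.abs(state.supply / np.maximum(baseline.production, 1e-12) - 1.0).max()
    model.calibration_residual = float(max(rel_p, rel_q))
    return model


# ---------------------------------------------------------------------------
# behavioral blocks
# ---------------------------------------------------------------------------

def apply_price_transmission(origin_price, tau):
    """Landed price after the ad-valorem wedge: ``origin * (1 + tau)``.

    The wedge revenue, ``tau * origin_price`` per unit, accrues to the
    destination government account.
    """
    tau = np.asarray(tau, float)
    if (tau < 0).any():
        raise ValueError("wedges must be non-negative")
    return np.asarray(origin_price, float) * (1.0 + tau)


def ces_price_index(value_shares, price_ratios, sigma, axis=0):
    """CES price index (relative to base) from base value shares and price ratios.

    Uses the log (Cobb-Douglas) limit at ``sigma == 1``.  Shares summing to
    zero along ``axis`` (empty nest) give an index of 1.
    """
    shares = np.asarray(value_shares, float)
    r = np.asarray(price_ratios, float)
    sigma = np.asarray(sigma, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_index = np.where(
            sigma == 1.0,
            (shares * np.log(np.maximum(r, 1e-300))).sum(axis=axis),
            np.log(np.maximum((shares * r ** (1.0 - sigma)).sum(axis=axis), 1e-300))
            / np.where(sigma == 1.0, 1.0, 1.0 - sigma),
        )
    empty = np.asarray(shares.sum(axis=axis) == 0)
    return np.where(empty, 1.0, np.exp(log_index))


def armington_allocate(total_demand, domestic_price_ratio, import_price_ratios,
                       dom_value_share0, import_value_shares0,
                       base_domestic, base_imports_bilateral,
                       sigma1, sigma2):
    """Two-level CES allocation of composite demand in calibrated share form.

    Parameters are the baseline value shares (the CES weights), baseline
    quantities and current-to-base price ratios; returns
    ``(domestic_qty, bilateral_import_qtys, composite_price_ratio)``.
    """
    import_ratios = np.asarray(import_price_ratios, float)
    bil0 = np.asarray(base_imports_bilateral, float)
    r_m = ces_price_index(import_value_shares0, import_ratios, sigma2, axis=0)
    shares_top = np.stack([np.asarray(dom_value_share0, float), 1.0 - np.asarray(dom_value_share0, float)])
    ratios_top = np.stack([np.asarray(domestic_price_ratio, float), r_m])
    r_c = ces_price_index(shares_top, ratios_top, sigma1, axis=0)
    base_total = np.asarray(base_domestic, float) + bil0.sum(axis=0)
    scale = np.asarray(total_demand, float) / np.where(base_total > 0, base_total, 1.0)
    dom = np.asarray(base_domestic, float) * (np.asarray(domestic_price_ratio, float) / r_c) ** (-sigma1) * scale
    m_scale = (r_m / r_c) ** (-sigma1) * scale
    bil = bil0 * (import_ratios / r_m) ** (-sigma2) * m_scale
    return dom, bil, r_c


def supply_response(model: CalibratedModel, price_ratio: np.ndarray,
                    multiplier: np.ndarray):
    """Supply quantities, land allocation and realized yields at given prices.

    ``price_ratio`` and ``multiplier`` are (n, c) arrays relative to base.
    Returns ``(supply, area, realized_yield, return_index)``.
    """
    b = model.baseline
    r = np.asarray(price_ratio, float)
    m = np.asarray(multiplier, float)
    if (r <= 0).any():
        raise ValueError("prices must be strictly positive")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("yield multipliers must lie in [0, 1]")
    returns = m * r ** (1.0 + b.eta)              # per-hectare revenue ratio
    rbar = (model.area_share0 * returns).sum(axis=1)
    supply = b.production * m * r ** b.eps_s * rbar[:, None] ** b.land_elasticity[:, None]
    realized_yield = model.yield0 * m * r ** b.eta
    area = np.where(realized_yield > 0, supply / np.where(realized_yield > 0, realized_yield, 1.0), 0.0)
    return supply, area, realized_yield, rbar


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EquilibriumState:
    """A converged market state plus solver diagnostics."""

    region_ids: list[str]
    commodity_ids: list[str]
    multiplier: np.ndarray       # (n, c) applied yield multipliers
    producer_price: np.ndarray   # (n, c)
    consumer_price: np.ndarray   # (n, c) composite
    composite_ratio: np.ndarray  # (n, c) consumer price index relative to base
    supply: np.ndarray           # (n, c)
    demand: np.ndarray           # (n, c) composite consumption
    dom_use: np.ndarray          # (n, c)
    flows: np.ndarray            # (o, d, c)
    area: np.ndarray             # (n, c)
    land: np.ndarray             # (n,) total cropland
    realized_yield: np.ndarray   # (n, c)
    iterations: int
    max_residual: float
    converged: bool
    residual_trajectory: list[float]

    def price_frame(self) -> pd.DataFrame:
        n, c = self.producer_price.shape
        return pd.DataFrame({
            "region_id": np.repeat(self.region_ids, c),
            "commodity_id": np.tile(self.commodity_ids, n),
            "producer_price": self.producer_price.ravel(),
            "consumer_price": self.consumer_price.ravel(),
            "supply": self.supply.ravel(),
            "demand": self.demand.ravel(),
            "area": self.area.ravel(),
            "realized_yield": self.realized_yield.ravel(),
        })


def _multiplier_array(model: CalibratedModel, shocks: pd.DataFrame | None,
                      column: str = "s_mean") -> np.ndarray:
    n, c = model.baseline.production.shape
    m = np.ones((n, c))
    if shocks is None:
        return m
    ridx = {r: i for i, r in enumerate(model.region_ids)}
    cidx = {k: i for i, k in enumerate(model.commodity_ids)}
    for row in shocks.itertuples(index=False):
        i = ridx.get(row.region_id)
        j = cidx.get(row.commodity_id)
        if i is None or j is None:
            continue
        s = getattr(row, column)
        if not 0.0 <= s <= 0.999:
            raise ValueError(f"shock {s} outside [0, 0.999] for {row.region_id}/{row.commodity_id}")
        m[i, j] = 1.0 - s
    return m


def solve_equilibrium(
    model: CalibratedModel,
    shocks: pd.DataFrame | None = None,
    shock_multiplier: np.ndarray | None = None,
    shock_column: str = "s_mean",
    tol: float = 1e-6,
    damping: float = 0.5,
    max_iter: int = 500,
) -> EquilibriumState:
    """Clear all markets under the given yield multipliers.

    ``shocks`` is a tidy shock table (``region_id, commodity_id, s_*``);
    alternatively pass a dense ``shock_multiplier`` array.  Iterates damped
    log-price updates until the largest relative market-clearing residual
    falls below ``tol``; raises :class:`ConvergenceError` after ``max_iter``.
    """
    b = model.baseline
    if shock_multiplier is not None:
        m = np.asarray(shock_multiplier, float)
    else:
        m = _multiplier_array(model, shocks, shock_column)
    n, c = b.production.shape
    lnr = np.zeros((n, c))
    # diagonal Jacobian guess: own supply slope + demand-side substitution
    sigma_max = np.maximum(b.sigma1, b.sigma2).max(axis=0)   # (c,)
    jac = b.eps_s + np.abs(b.eps_d) + sigma_max[None, :]
    trajectory: list[float] = []
    converged = False
    iterations = 0
    residual = np.inf
    for iterations in range(max_iter + 1):
        r = np.exp(lnr)
        supply, area, realized_yield, _ = supply_response(model, r, m)
        # demand side: price ratio of origin o's good is r[o, c] everywhere
        # (ad-valorem wedges cancel in the ratio)
        import_ratios = np.broadcast_to(r[:, None, :], (n, n, c))
        r_m = ces_price_index(model.import_value_share0, import_ratios, b.sigma2, axis=0)
        shares_top = np.stack([model.dom_value_share0, 1.0 - model.dom_value_share0])
        ratios_top = np.stack([r, r_m])
        r_c = ces_price_index(shares_top, ratios_top, b.sigma1, axis=0)
        demand = b.demand * r_c ** b.eps_d
        scale = demand / np.where(b.demand > 0, b.demand, 1.0)
        dom_use = model.dom_use0 * (r / r_c) ** (-b.sigma1) * scale
        m_scale = (r_m / r_c) ** (-b.sigma1) * scale
        flows = b.flows * (import_ratios / r_m[None, :, :]) ** (-b.sigma2[None, :, :]) * m_scale[None, :, :]
        goods_demand = dom_use + flows.sum(axis=1)
        active = supply > 1e-300
        ratio = np.where(active, goods_demand / np.where(active, supply, 1.0), 1.0)
        residual = float(np.abs(ratio - 1.0).max())
        trajectory.append(residual)
        if residual <= tol:
            converged = True
            break
        lnr = lnr + damping * np.log(np.maximum(ratio, 1e-12)) / jac
    if not converged:
        raise ConvergenceError(
            f"market solver did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})",
            trajectory,
        )
    return EquilibriumState(
        region_ids=model.region_ids,
        commodity_ids=model.commodity_ids,
        multiplier=m,
        producer_price=b.producer_price * np.exp(lnr),
        consumer_price=b.consumer_price * r_c,
        composite_ratio=r_c,
        supply=supply,
        demand=demand,
        dom_use=dom_use,
        flows=flows,
        area=area,
        land=area.sum(axis=1),
        realized_yield=realized_yield,
        iterations=iterations,
        max_residual=residual,
        converged=True,
        residual_trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# indicators and aggregation
# ---------------------------------------------------------------------------

def compute_trade_indicators(
    production: np.ndarray,
    demand: np.ndarray,
    flows: np.ndarray,
    region_mask: np.ndarray,
    commodity_ids: list[str],
) -> pd.DataFrame:
    """Self-sufficiency, export intensity and import penetration (percent)
    for the bloc selected by ``region_mask``, excluding intra-bloc flows.

    Zero denominators yield NaN and ``defined = False`` rather than 0.
    """
    mask = np.asarray(region_mask, bool)
    prod = production[mask].sum(axis=0)
    dem = demand[mask].sum(axis=0)
    exports = flows[np.ix_(mask, ~mask)].sum(axis=(0, 1))
    imports = flows[np.ix_(~mask, mask)].sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ssr = np.where(dem > 0, 100.0 * prod / np.where(dem > 0, dem, 1.0), np.nan)
        exp_int = np.where(prod > 0, 100.0 * exports / np.where(prod > 0, prod, 1.0), np.nan)
        imp_pen = np.where(dem > 0, 100.0 * imports / np.where(dem > 0, dem, 1.0), np.nan)
    return pd.DataFrame({
        "commodity_id": commodity_ids,
        "self_sufficiency_pct": ssr,
        "export_intensity_pct": exp_int,
        "import_penetration_pct": imp_pen,
        "defined": (dem > 0) & (prod > 0),
    })


def aggregate_outputs(
    model: CalibratedModel,
    state: EquilibriumState,
    groups: dict[str, list[str]],
    blocs: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Percent changes by commodity group and region bloc.

    Yield, production and producer-price changes are weighted by base
    production value; land-use changes aggregate physical area.
    """
    b = model.baseline
    cidx = {k: i for i, k in enumerate(model.commodity_ids)}
    rows = []
    for bloc_name, mask in blocs.items():
        mask = np.asarray(mask, bool)
        for group_name, members in groups.items():
            js = [cidx[m] for m in members if m in cidx]
            if not js:
                raise ValueError(f"commodity group '{group_name}' is empty")
            w = (b.production * b.producer_price)[np.ix_(mask, js)]
            if w.sum() <= 0:
                raise ValueError(f"group '{group_name}' has no base production value in bloc '{bloc_name}'")
            w = w / w.sum()

            def wchange(new, old):
                rel = new[np.ix_(mask, js)] / np.where(old[np.ix_(mask, js)] > 0, old[np.ix_(mask, js)], 1.0) - 1.0
                return float((w * rel).sum() * 100.0)

            area_old = b.area[np.ix_(mask, js)].sum()
            area_new = state.area[np.ix_(mask, js)].sum()
            rows.append({
                "bloc": bloc_name,
                "group": group_name,
                "yield_pct": wchange(state.realized_yield, model.yield0),
                "production_pct": wchange(state.supply, b.production),
                "producer_price_pct": wchange(state.producer_price, b.producer_price),
                "land_pct": float((area_new / area_old - 1.0) * 100.0) if area_old > 0 else np.nan,
            })
    return pd.DataFrame(rows)
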