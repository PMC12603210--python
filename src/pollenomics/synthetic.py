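"""Synthetic input data emulating the real dependence/market databases.

The generator produces a complete, internally consistent multi-region
agri-food dataset — regions, commodities, a balanced base-year market with
bilateral trade, elasticities, crop-level dependence tables and nutrient
coefficients — sized so the full pipeline (shocks -> equilibrium -> welfare ->
nutrition -> sensitivity grid) runs in seconds.  It emulates the statistical
shape of the real sources (right-skewed production values, dependence ratios
in [0, 1] with ordered bounds, inelastic demand, globally balanced bilateral
trade, Europe holding roughly a tenth of the world's pollination-dependent
production value) without attempting to match any real country.

Everything is driven by a single integer seed through
:func:`numpy.random.default_rng`, so identical configs give identical data on
any platform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

COMMODITY_GROUPS = ("vegetables_fruits", "cereals", "oilseeds", "other")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Shape and dispersion parameters of the generated world."""

    seed: int
    n_regions_europe: int = 3
    n_regions_eu: int = 2
    n_regions_extra: int = 3
    n_commodities: int = 6
    n_pollination_dependent: int = 3
    europe_dependent_value_share: float = 0.10
    value_sigma: float = 0.8          # log-scale dispersion of demand/production values
    price_sigma: float = 0.25
    import_penetration: tuple[float, float] = (0.10, 0.35)
    eps_s_range: tuple[float, float] = (0.3, 0.8)
    eps_d_range: tuple[float, float] = (-0.8, -0.2)   # inelastic food demand
    sigma1_range: tuple[float, float] = (2.0, 4.0)
    sigma2_range: tuple[float, float] = (4.0, 8.0)
    eta: float = 0.2                  # price-responsive yield (intensification)
    land_elasticity: float = 0.1      # total cropland response to returns
    tau_max: float = 0.20
    full_dependence_fraction: float = 0.0   # fraction of crops forced to D = 1
    include_fallback_crop: bool = True      # one crop without D_min/D_max

    def __post_init__(self) -> None:
        if self.n_regions_europe < 1 or self.n_regions_extra < 1:
            raise ValueError("need at least one European and one extra-European region")
        if self.n_regions_eu > self.n_regions_europe:
            raise ValueError("EU regions must be a subset of European regions")
        if self.n_pollination_dependent > self.n_commodities:
            raise ValueError("more pollination-dependent commodities than commodities")
        if self.n_commodities < 1:
            raise ValueError("need at least one commodity")
        if not 0 < self.europe_dependent_value_share < 1:
            raise ValueError("europe_dependent_value_share must lie in (0, 1)")


@dataclasses.dataclass
class SyntheticDataset:
    """All input tables consumed by the pipeline stages."""

    regions: pd.DataFrame          # region_id, in_europe, in_eu, gdp, population, households, land_endowment, land_elasticity
    commodities: pd.DataFrame      # commodity_id, pollination_dependent, group
    market: pd.DataFrame           # region_id, commodity_id, production_qty, demand_qty, producer_price, consumer_price
    trade: pd.DataFrame            # origin, destination, commodity_id, qty
    wedges: pd.DataFrame           # origin, destination, commodity_id, tau
    elasticities: pd.DataFrame     # region_id, commodity_id, eps_s, eps_d, eta, sigma1, sigma2
    dependence: pd.DataFrame       # crop_id, D_mean, D_min, D_max, source_tag
    dependence_alt: pd.DataFrame   # older-vintage style alternative (mostly lower D)
    wild_contribution: pd.DataFrame  # commodity_id, phi, is_average_imputed
    production_values: pd.DataFrame  # region_id, commodity_id, crop_id, value_eur (Europe only)
    nutrients: pd.DataFrame        # commodity_id, kcal_per_ton, vitA_per_ton, folate_per_ton

    @property
    def europe_regions(self) -> set[str]:
        return set(self.regions.loc[self.regions["in_europe"], "region_id"])

    @property
    def all_regions(self) -> set[str]:
        return set(self.regions["region_id"])


def _commodity_names(n: int, n_dep: int) -> tuple[list[str], list[str]]:
    dep_pool = ["rapeseed", "vegetables", "fruits", "sunflower", "pulses", "citrus"]
    indep_pool = ["cereals", "roots", "meat_dairy", "sugar", "fodder", "rice"]
    dep_groups = ["oilseeds", "vegetables_fruits", "vegetables_fruits",
                  "oilseeds", "other", "vegetables_fruits"]
    indep_groups = ["cereals", "other", "other", "other", "other", "cereals"]
    if n_dep > len(dep_pool) or n - n_dep > len(indep_pool):
        dep_pool = [f"dep_{i:02d}" for i in range(n_dep)]
        indep_pool = [f"indep_{i:02d}" for i in range(n - n_dep)]
        dep_groups = ["vegetables_fruits"] * n_dep
        indep_groups = ["cereals"] * (n - n_dep)
    names = dep_pool[:n_dep] + indep_pool[: n - n_dep]
    groups = dep_groups[:n_dep] + indep_groups[: n - n_dep]
    return names, groups


def generate_market_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete balanced dataset from a seeded config."""
    rng = np.random.default_rng(config.seed)
    n_eur, n_eu, n_extra = config.n_regions_europe, config.n_regions_eu, config.n_regions_extra
    n_reg = n_eur + n_extra
    n_com = config.n_commodities
    n_dep = config.n_pollination_dependent

    region_ids = (
        [f"EU{i + 1:02d}" for i in range(n_eu)]
        + [f"EUR{i + 1:02d}" for i in range(n_eur - n_eu)]
        + [f"EXT{i + 1:02d}" for i in range(n_extra)]
    )
    in_europe = np.array([True] * n_eur + [False] * n_extra)
    in_eu = np.array([True] * n_eu + [False] * (n_reg - n_eu))
    com_ids, com_groups = _commodity_names(n_com, n_dep)
    dependent = np.array([True] * n_dep + [False] * (n_com - n_dep))

    # region economic size: right-skewed; extra-European world is larger in
    # aggregate so Europe ends up a modest share of global production value
    size = np.exp(rng.normal(0.0, 0.5, n_reg))
    size[~in_europe] *= 3.0 * n_eur / max(n_extra, 1)

    # base-year demand quantities (kt) and producer prices (EUR/t)
    base_price = np.exp(rng.normal(np.log(400.0), 0.4, n_com))
    demand = np.exp(rng.normal(np.log(2000.0), config.value_sigma, (n_reg, n_com))) * size[:, None]
    price = base_price[None, :] * np.exp(rng.normal(0.0, config.price_sigma, (n_reg, n_com)))

    # bilateral import structure: penetration per destination-commodity and
    # origin weights proportional to exporter size, biased toward intra-bloc
    # partners (continental trade costs)
    mu = rng.uniform(*config.import_penetration, (n_reg, n_com))
    origin_w = size[:, None, None] * np.exp(rng.normal(0.0, 0.6, (n_reg, n_reg, n_com)))
    same_bloc = in_europe[:, None] == in_europe[None, :]
    origin_w *= np.where(same_bloc, 3.0, 1.0)[:, :, None]
    for d in range(n_reg):
        origin_w[d, d, :] = 0.0  # origin axis first: origin_w[o, d, c]
    origin_w /= origin_w.sum(axis=0, keepdims=True)

    # Rescale extra-European demand so Europe holds exactly the target share
    # of the global value of pollination-dependent production.  With fixed
    # origin weights every flow is linear in destination demand, so the
    # scale factor solves a linear equation.
    target = config.europe_dependent_value_share
    flows = mu[None, :, :] * demand[None, :, :] * origin_w      # [o, d, c]
    dom_use = (1.0 - mu) * demand
    dep_val = price[:, dependent]

    def _val(qty):  # production value of dependent commodities by origin
        return (qty[:, dependent] * dep_val)

    exports_to_eur = flows[:, in_europe, :].sum(axis=1)
    exports_to_ext = flows[:, ~in_europe, :].sum(axis=1)
    fixed_e = _val(dom_use)[in_europe].sum() + _val(exports_to_eur)[in_europe].sum()
    lin_e = _val(exports_to_ext)[in_europe].sum()         # scales with f
    fixed_x = _val(exports_to_eur)[~in_europe].sum()
    lin_x = _val(dom_use)[~in_europe].sum() + _val(exports_to_ext)[~in_europe].sum()
    # (1-t)(fixed_e + lin_e f) = t (fixed_x + lin_x f)
    denom = target * lin_x - (1.0 - target) * lin_e
    if denom <= 0:
        raise ValueError("cannot reach the configured European value share with this config")
    factor = ((1.0 - target) * fixed_e - target * fixed_x) / denom
    if factor <= 0:
        raise ValueError("cannot reach the configured European value share with this config")
    demand[~in_europe] *= factor

    flows = mu[None, :, :] * demand[None, :, :] * origin_w
    dom_use = (1.0 - mu) * demand
    production = dom_use + flows.sum(axis=1)

    tau = rng.uniform(0.0, config.tau_max, (n_reg, n_reg, n_com))
    for d in range(n_reg):
        tau[d, d, :] = 0.0

    # composite consumer price = unit expenditure on domestic + landed imports
    landed_value = (flows * (price[:, None, :] * (1.0 + tau))).sum(axis=0)
    consumer_price = (dom_use * price + landed_value) / demand

    gdp = size * 1.0e12 * np.exp(rng.normal(0.0, 0.2, n_reg))
    population = size * 8.0e7 * np.exp(rng.normal(0.0, 0.2, n_reg))
    households = population / rng.uniform(2.0, 2.6, n_reg)
    # cropland and endowment; area shares follow production value with noise
    value = production * price
    area_w = value * np.exp(rng.normal(0.0, 0.3, (n_reg, n_com)))
    cropland = size * 2.0e4 * np.exp(rng.normal(0.0, 0.3, n_reg))
    area = area_w / area_w.sum(axis=1, keepdims=True) * cropland[:, None]
    land_endowment = cropland * rng.uniform(1.2, 1.5, n_reg)

    regions = pd.DataFrame({
        "region_id": region_ids,
        "in_europe": in_europe,
        "in_eu": in_eu,
        "gdp": gdp,
        "population": population,
        "households": households,
        "cropland": cropland,
        "land_endowment": land_endowment,
        "land_elasticity": config.land_elasticity,
    })
    commodities = pd.DataFrame({
        "commodity_id": com_ids,
        "pollination_dependent": dependent,
        "group": com_groups,
    })
    reg_idx = np.repeat(region_ids, n_com)
    com_idx = np.tile(com_ids, n_reg)
    market = pd.DataFrame({
        "region_id": reg_idx,
        "commodity_id": com_idx,
        "production_qty": production.ravel(),
        "demand_qty": demand.ravel(),
        "producer_price": price.ravel(),
        "consumer_price": consumer_price.ravel(),
        "area": area.ravel(),
    })
    o_idx, d_idx, c_idx = np.meshgrid(range(n_reg), range(n_reg), range(n_com), indexing="ij")
    trade = pd.DataFrame({
        "origin": np.asarray(region_ids)[o_idx.ravel()],
        "destination": np.asarray(region_ids)[d_idx.ravel()],
        "commodity_id": np.asarray(com_ids)[c_idx.ravel()],
        "qty": flows.ravel(),
    })
    trade = trade[trade["origin"] != trade["destination"]].reset_index(drop=True)
    wedges = pd.DataFrame({
        "origin": np.asarray(region_ids)[o_idx.ravel()],
        "destination": np.asarray(region_ids)[d_idx.ravel()],
        "commodity_id": np.asarray(com_ids)[c_idx.ravel()],
        "tau": tau.ravel(),
    })
    wedges = wedges[wedges["origin"] != wedges["destination"]].reset_index(drop=True)
    elasticities = pd.DataFrame({
        "region_id": reg_idx,
        "commodity_id": com_idx,
        "eps_s": rng.uniform(*config.eps_s_range, (n_reg, n_com)).ravel(),
        "eps_d": rng.uniform(*config.eps_d_range, (n_reg, n_com)).ravel(),
        "eta": config.eta,
        "sigma1": np.repeat(rng.uniform(*config.sigma1_range, n_com)[None, :], n_reg, 0).ravel(),
        "sigma2": np.repeat(rng.uniform(*config.sigma2_range, n_com)[None, :], n_reg, 0).ravel(),
    })

    dependence, dependence_alt, wild, prod_values = generate_dependence_tables(
        config, regions, commodities, market, rng
    )
    nutrients = generate_nutrient_table(config, commodities, rng)
    return SyntheticDataset(
        regions=regions,
        commodities=commodities,
        market=market,
        trade=trade,
        wedges=wedges,
        elasticities=elasticities,
        dependence=dependence,
        dependence_alt=dependence_alt,
        wild_contribution=wild,
        production_values=prod_values,
        nutrients=nutrients,
    )


def generate_dependence_tables(
    config: SyntheticConfig,
    regions: pd.DataFrame,
    commodities: pd.DataFrame,
    market: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Crop dependence ratios, wild-pollinator shares and crop value splits.

    Multi-crop commodities exercise value-share aggregation; optionally one
    crop lacks min/max bounds (fallback path) and a configurable fraction is
    fully dependent (D = 1) to exercise the 99.9% shock cap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    dep_coms = commodities.loc[commodities["pollination_dependent"], "commodity_id"].tolist()
    eur_regions = regions.loc[regions["in_europe"], "region_id"].tolist()

    crop_rows, share_rows = [], []
    crops_per = [1 + (i % 3) for i in range(len(dep_coms))]  # mix of single- and multi-crop
    crop_counter = 0
    for com, k in zip(dep_coms, crops_per):
        crop_ids = [f"{com}_crop{j + 1}" for j in range(k)]
        for cid in crop_ids:
            d_mean = float(rng.beta(2.0, 2.5))
            if rng.uniform() < config.full_dependence_fraction:
                d_mean = 1.0
            d_min = d_mean * float(rng.uniform(0.3, 0.9))
            d_max = d_mean + (1.0 - d_mean) * float(rng.uniform(0.1, 0.6))
            crop_rows.append((cid, d_mean, d_min, d_max, "synthetic"))
            crop_counter += 1
        # split each European region's production value across member crops
        base = market.merge(regions[["region_id", "in_europe"]], on="region_id")
        base = base[(base["commodity_id"] == com) & base["in_europe"]]
        for _, row in base.iterrows():
            w = rng.dirichlet(np.full(k, 2.0))
            total_value = row["production_qty"] * row["producer_price"]
            for cid, wi in zip(crop_ids, w):
                share_rows.append((row["region_id"], com, cid, total_value * wi))

    dependence = pd.DataFrame(
        crop_rows, columns=["crop_id", "D_mean", "D_min", "D_max", "source_tag"]
    )
    if config.include_fallback_crop and len(dependence):
        dependence.loc[dependence.index[-1], ["D_min", "D_max"]] = np.nan

    # alternative older-vintage table: same crops, mostly lower ratios
    alt = dependence.copy()
    scale = rng.uniform(0.55, 0.95, len(alt))
    for col in ("D_mean", "D_min", "D_max"):
        alt[col] = np.clip(alt[col] * scale, 0.0, 1.0)
    alt["source_tag"] = "synthetic_alt"

    wild = pd.DataFrame({
        "commodity_id": dep_coms,
        "phi": rng.uniform(0.15, 0.75, len(dep_coms)),
        "is_average_imputed": False,
    })
    production_values = pd.DataFrame(
        share_rows, columns=["region_id", "commodity_id", "crop_id", "value_eur"]
    )
    assert set(production_values["region_id"]) <= set(eur_regions)
    return dependence, alt, wild, production_values


def generate_nutrient_table(
    config: SyntheticConfig,
    commodities: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nutrient coefficients with vitamin A and folate concentrated in
    vegetables and fruits, kilocalories spread across all groups."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(commodities)
    veg = (commodities["group"] == "vegetables_fruits").to_numpy()
    # vegetables and fruits are calorie-light but nutrient-dense
    kcal = rng.uniform(1.5e6, 3.5e6, n) * np.where(veg, 0.2, 1.0)  # kcal per product ton
    vita = rng.uniform(1.0, 10.0, n) * np.where(veg, 40.0, 1.0)   # RE-like units/t
    folate = rng.uniform(10.0, 60.0, n) * np.where(veg, 8.0, 1.0)
    return pd.DataFrame({
        "commodity_id": commodities["commodity_id"],
        "kcal_per_ton": kcal,
        "vitA_per_ton": vita,
        "folate_per_ton": folate,
    })


def generate_vote_table(
    welfare_share_of_gdp: pd.Series,
    seed: int,
    slope: float = -8.0,
    noise: float = 0.05,
) -> pd.DataFrame:
    """Synthetic roll-call rejection shares for EU member regions.

    Rejection shares are a planted linear function of consumer-welfare change
    (share of GDP, negative = loss) plus noise, clipped to [0, 1] — enough to
    exercise the population-weighted association analysis end to end.
    """
    rng = np.random.default_rng(seed)
    x = welfare_share_of_gdp.to_numpy(float)
    base = 0.35 + slope * x
    out = pd.DataFrame({
        "member_state": welfare_share_of_gdp.index,
        "rejection_share_nrl": np.clip(base + rng.normal(0, noise, len(x)), 0, 1),
        "rejection_share_sur": np.clip(base + 0.05 + rng.normal(0, noise, len(x)), 0, 1),
        "population": rng.uniform(1e6, 8e7, len(x)),
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# printed commodity table for Europe (read-only worked-example fixture)
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    # commodity, group, europe_share_global_pct, value_share_europe_pct,
    # self_sufficiency_pct, export_intensity_pct, import_penetration_pct,
    # D_mean_pct, phi_pct, shock_mean_pct, shock_low_pct, shock_high_pct,
    # bounds_fallback, phi_imputed
    ("Other Cereals", "other_cereals_crops", 13.7, 1.6, 76.3, 0.3, 23.9, 18.7, 23.0, 4.3, 2.2, 6.5, True, False),
    ("Pulses", "other_cereals_crops", 9.1, 2.2, 103.4, 13.1, 10.2, 9.2, 76.0, 7.0, 4.2, 9.1, False, False),
    ("Rapeseed", "oilseeds", 32.6, 6.0, 87.3, 26.6, 35.9, 27.0, 59.6, 16.1, 4.1, 36.1, False, False),
    ("Sunflower", "oilseeds", 64.7, 5.9, 104.6, 11.1, 7.0, 54.0, 14.7, 7.9, 2.6, 12.3, False, False),
    ("Soya", "oilseeds", 5.0, 2.0, 50.2, 18.0, 58.8, 19.0, 50.4, 9.6, 2.1, 16.6, False, True),
    ("Tomatoes", "vegetables_fruits", 24.8, 16.0, 99.0, 7.8, 8.7, 27.0, 50.4, 13.6, 3.0, 23.3, False, True),
    ("Other Vegetables", "vegetables_fruits", 7.5, 39.3, 91.3, 1.6, 10.2, 38.1, 76.0, 28.9, 25.3, 32.2, False, False),
    ("Apples", "vegetables_fruits", 14.5, 5.3, 93.7, 8.3, 14.1, 66.6, 42.9, 28.6, 7.2, 37.1, False, False),
    ("Citrus Fruits", "vegetables_fruits", 6.1, 2.9, 45.4, 2.0, 55.5, 51.3, 15.5, 8.0, 6.1, 9.7, False, False),
    ("Other Fruits", "vegetables_fruits", 8.0, 18.8, 57.7, 9.1, 47.5, 61.0, 48.1, 29.4, 23.1, 33.3, False, False),
]

_TABLE1_COLUMNS = [
    "commodity", "group", "europe_share_global_pct", "value_share_europe_pct",
    "self_sufficiency_pct", "export_intensity_pct", "import_penetration_pct",
    "D_mean_pct", "phi_pct", "shock_mean_pct", "shock_low_pct", "shock_high_pct",
    "bounds_fallback", "phi_imputed",
]


def table1_fixture() -> pd.DataFrame:
    """The ten pollination-dependent European commodity accounts.

    Europe-aggregate dependence ratios, wild-pollinator contribution shares,
    trade indicators and the resulting mean/low/high productivity shocks, all
    in percent as published.  ``bounds_fallback`` marks the commodity whose
    confidence bounds come from the +/-50% fallback (single pseudo-cereal
    crop with no interval data); ``phi_imputed`` marks commodities whose wild
    contribution is the cross-crop average (no crop-specific measurements).
    """
    df = pd.DataFrame(_TABLE1_ROWS, columns=_TABLE1_COLUMNS)
    return df.set_index("commodity", drop=False)
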