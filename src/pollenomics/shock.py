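"""Productivity shocks from a collapse of wild pollinators.

The shock applied to a commodity ``c`` in region ``n`` is

    s_{c,n} = min(cap, sum_i shr_{c,i,n} * phi_c * D_i)

where ``D_i`` is the dependence ratio of crop ``i`` on animal-mediated
pollination (0 = none, 1 = total), ``phi_c`` is the share of that pollination
service delivered by *wild* (as opposed to managed) pollinators, and
``shr_{c,i,n}`` is the production-value share of crop ``i`` within commodity
``c`` in region ``n``.  The corresponding yield multiplier is ``1 - s``.
Crops that are fully dependent (D = 1, phi = 1) are capped at a 99.9% shock so
yields never reach exactly zero.

95% confidence bounds are obtained by replacing each crop's dependence ratio
with the 2.5%/97.5% quantiles of a triangular distribution spanning
(D_min, D_mean, D_max), aggregated comonotonically (every crop evaluated at
the same quantile).  Crops without reported min/max fall back to a +/-50%
variation around their mean contribution.

Tables are plain :class:`pandas.DataFrame` objects with documented schemas:

* dependence: ``crop_id, D_mean, D_min, D_max[, source_tag]``
* wild contribution: ``commodity_id, phi[, is_average_imputed]``
* production values: ``region_id, commodity_id, crop_id, value_eur``
* value shares: ``region_id, commodity_id, crop_id, share``
* shocks: ``region_id, commodity_id, s_mean, s_low, s_high,
  multiplier_mean, multiplier_low, multiplier_high``
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._util import require_columns, round_half_up

SHOCK_CAP = 0.999
"""Maximum admissible productivity shock (fully dependent crops)."""


# ---------------------------------------------------------------------------
# crop -> commodity value shares
# ---------------------------------------------------------------------------

def map_crops_to_commodities(production_values: pd.DataFrame) -> pd.DataFrame:
    """Normalize crop production values into per-(region, commodity) shares.

    Parameters
    ----------
    production_values
        Columns ``region_id, commodity_id, crop_id, value_eur``; values are
        base-year production values. Each crop must belong to exactly one
        commodity.

    Returns
    -------
    DataFrame with columns ``region_id, commodity_id, crop_id, share`` where
    shares sum to one within each (region, commodity).  Region-commodity
    cells whose total value is zero are dropped with a warning.
    """
    require_columns(
        production_values,
        ["region_id", "commodity_id", "crop_id", "value_eur"],
        "production_values",
    )
    values = production_values.copy()
    if (values["value_eur"] < 0).any():
        bad = values.loc[values["value_eur"] < 0, "crop_id"].unique()
        raise ValueError(f"negative production values for crops: {list(bad)}")
    crop_map = values.groupby("crop_id")["commodity_id"].nunique()
    multi = crop_map[crop_map > 1]
    if len(multi):
        raise ValueError(
            f"crops mapped to more than one commodity: {list(multi.index)}"
        )
    totals = values.groupby(["region_id", "commodity_id"])["value_eur"].transform("sum")
    zero = totals == 0
    if zero.any():
        dropped = values.loc[zero, ["region_id", "commodity_id"]].drop_duplicates()
        warnings.warn(
            "dropping zero-value region-commodity cells: "
            + ", ".join(f"{r}/{c}" for r, c in dropped.itertuples(index=False)),
            stacklevel=2,
        )
        values = values.loc[~zero]
        totals = totals.loc[~zero]
    out = values[["region_id", "commodity_id", "crop_id"]].copy()
    out["share"] = (values["value_eur"] / totals).to_numpy()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# triangular distribution helpers (thin wrappers over scipy.stats.triang)
# ---------------------------------------------------------------------------

def _triang(a: float, c: float, b: float):
    if not (a <= c <= b):
        raise ValueError(f"triangular parameters must satisfy a <= c <= b, got {(a, c, b)}")
    return stats.triang(c=(c - a) / (b - a), loc=a, scale=b - a)


def triangular_quantile(a: float, c: float, b: float, p: float) -> float:
    """Quantile of the triangular distribution with support [a, b], mode c."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if a > b:
        raise ValueError(f"lower bound {a} exceeds upper bound {b}")
    if b == a:
        return float(a)  # degenerate point mass
    return float(_triang(a, c, b).ppf(p))


def triangular_cdf(a: float, c: float, b: float, x: float) -> float:
    """CDF of the triangular distribution with support [a, b], mode c."""
    if a > b:
        raise ValueError(f"lower bound {a} exceeds upper bound {b}")
    if b == a:
        return 0.0 if x < a else 1.0
    return float(_triang(a, c, b).cdf(x))


# ---------------------------------------------------------------------------
# commodity shocks
# ---------------------------------------------------------------------------

def _validate_inputs(shares: pd.DataFrame, phi: pd.DataFrame, dependence: pd.DataFrame) -> None:
    require_columns(shares, ["region_id", "commodity_id", "crop_id", "share"], "shares")
    require_columns(phi, ["commodity_id", "phi"], "phi")
    require_columns(dependence, ["crop_id", "D_mean"], "dependence")
    if ((phi["phi"] < 0) | (phi["phi"] > 1)).any():
        raise ValueError("phi values must lie in [0, 1]")
    if ((dependence["D_mean"] < 0) | (dependence["D_mean"] > 1)).any():
        raise ValueError("dependence ratios must lie in [0, 1]")
    if ((shares["share"] < 0) | (shares["share"] > 1 + 1e-9)).any():
        raise ValueError("value shares must lie in [0, 1]")
    sums = shares.groupby(["region_id", "commodity_id"])["share"].sum()
    if (np.abs(sums - 1.0) > 1e-6).any():
        bad = sums[np.abs(sums - 1.0) > 1e-6]
        raise ValueError(f"value shares do not sum to 1 for: {list(bad.index)}")
    dependent_crops = set(dependence.loc[dependence["D_mean"] > 0, "crop_id"])
    used = shares[shares["crop_id"].isin(dependent_crops)]
    missing_phi = set(used["commodity_id"]) - set(phi["commodity_id"])
    if missing_phi:
        raise ValueError(
            f"no wild-pollinator contribution phi for commodities with dependent crops: {sorted(missing_phi)}"
        )


def compute_commodity_shock(
    shares: pd.DataFrame,
    phi: pd.DataFrame,
    dependence: pd.DataFrame,
    cap: float = SHOCK_CAP,
) -> pd.DataFrame:
    """Mean productivity shock per (region, commodity).

    Returns columns ``region_id, commodity_id, s_mean, multiplier_mean``.
    Crops absent from the dependence table contribute zero (no pollination
    dependence).
    """
    _validate_inputs(shares, phi, dependence)
    merged = shares.merge(dependence[["crop_id", "D_mean"]], on="crop_id", how="left")
    merged["D_mean"] = merged["D_mean"].fillna(0.0)
    merged = merged.merge(phi[["commodity_id", "phi"]], on="commodity_id", how="left")
    merged["phi"] = merged["phi"].fillna(0.0)
    merged["contrib"] = merged["share"] * merged["phi"] * merged["D_mean"]
    out = (
        merged.groupby(["region_id", "commodity_id"], as_index=False)["contrib"]
        .sum()
        .rename(columns={"contrib": "s_mean"})
    )
    out["s_mean"] = out["s_mean"].clip(upper=cap)
    out["multiplier_mean"] = 1.0 - out["s_mean"]
    return out


def derive_shock_bounds(
    shares: pd.DataFrame,
    phi: pd.DataFrame,
    dependence: pd.DataFrame,
    coverage: float = 0.95,
    fallback_pct: float = 0.5,
    cap: float = SHOCK_CAP,
) -> pd.DataFrame:
    """Confidence bounds for the productivity shock.

    Each crop's dependence ratio is replaced by the triangular quantiles at
    (1 +/- coverage)/2 and aggregated with the mean formula, all crops at the
    same quantile (comonotone aggregation).  Crops whose ``D_min``/``D_max``
    are missing use their mean contribution scaled by ``1 -/+ fallback_pct``.

    Returns columns ``region_id, commodity_id, s_low, s_high,
    multiplier_low, multiplier_high``.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must lie in (0, 1), got {coverage}")
    _validate_inputs(shares, phi, dependence)
    dep = dependence.copy()
    for col in ("D_min", "D_max"):
        if col not in dep.columns:
            dep[col] = np.nan
    has_bounds = dep["D_min"].notna() & dep["D_max"].notna()
    bad = has_bounds & ~((dep["D_min"] <= dep["D_mean"]) & (dep["D_mean"] <= dep["D_max"]))
    if bad.any():
        raise ValueError(
            f"dependence bounds must satisfy D_min <= D_mean <= D_max: {list(dep.loc[bad, 'crop_id'])}"
        )
    p_low = (1.0 - coverage) / 2.0
    p_high = (1.0 + coverage) / 2.0
    d_low = np.empty(len(dep))
    d_high = np.empty(len(dep))
    for i, row in enumerate(dep.itertuples(index=False)):
        if np.isnan(row.D_min) or np.isnan(row.D_max):
            d_low[i] = np.nan  # flag: use fallback on the mean contribution
            d_high[i] = np.nan
        else:
            d_low[i] = triangular_quantile(row.D_min, row.D_mean, row.D_max, p_low)
            d_high[i] = triangular_quantile(row.D_min, row.D_mean, row.D_max, p_high)
    dep["D_low_q"], dep["D_high_q"] = d_low, d_high

    merged = shares.merge(
        dep[["crop_id", "D_mean", "D_low_q", "D_high_q"]], on="crop_id", how="left"
    )
    merged[["D_mean", ]] = merged[["D_mean"]].fillna(0.0)
    merged = merged.merge(phi[["commodity_id", "phi"]], on="commodity_id", how="left")
    merged["phi"] = merged["phi"].fillna(0.0)
    base = merged["share"] * merged["phi"]
    mean_contrib = base * merged["D_mean"]
    low = np.where(
        merged["D_low_q"].notna(), base * merged["D_low_q"], mean_contrib * (1.0 - fallback_pct)
    )
    high = np.where(
        merged["D_high_q"].notna(), base * merged["D_high_q"], mean_contrib * (1.0 + fallback_pct)
    )
    merged["low"], merged["high"] = low, high
    out = merged.groupby(["region_id", "commodity_id"], as_index=False)[["low", "high"]].sum()
    out = out.rename(columns={"low": "s_low", "high": "s_high"})
    out["s_low"] = out["s_low"].clip(upper=cap)
    out["s_high"] = out["s_high"].clip(upper=cap)
    out["multiplier_low"] = 1.0 - out["s_low"]
    out["multiplier_high"] = 1.0 - out["s_high"]
    return out


def build_shock_table(
    dependence: pd.DataFrame,
    phi: pd.DataFrame,
    value_shares: pd.DataFrame,
    europe_regions: set[str],
    all_regions: set[str] | None = None,
    coverage: float = 0.95,
    fallback_pct: float = 0.5,
    cap: float = SHOCK_CAP,
) -> pd.DataFrame:
    """Full shock table: Europe shocked, all other regions at zero.

    ``value_shares`` need only cover European regions; any region listed in
    ``all_regions`` but absent from the share table receives a zero shock.
    Regions in the share table that are neither European nor in
    ``all_regions`` are rejected (unclassified).
    """
    share_regions = set(value_shares["region_id"])
    if all_regions is None:
        all_regions = share_regions | set(europe_regions)
    unclassified = share_regions - set(all_regions)
    if unclassified:
        raise ValueError(f"regions not classified as European or extra-European: {sorted(unclassified)}")
    eu_shares = value_shares[value_shares["region_id"].isin(europe_regions)]
    mean = compute_commodity_shock(eu_shares, phi, dependence, cap=cap)
    bounds = derive_shock_bounds(
        eu_shares, phi, dependence, coverage=coverage, fallback_pct=fallback_pct, cap=cap
    )
    shocked = mean.merge(bounds, on=["region_id", "commodity_id"])

    commodities = sorted(set(value_shares["commodity_id"]))
    rows = []
    for region in sorted(set(all_regions) - set(europe_regions)):
        for com in commodities:
            rows.append((region, com))
    zero = pd.DataFrame(rows, columns=["region_id", "commodity_id"])
    for col in ("s_mean", "s_low", "s_high"):
        zero[col] = 0.0
    for col in ("multiplier_mean", "multiplier_low", "multiplier_high"):
        zero[col] = 1.0
    cols = [
        "region_id", "commodity_id", "s_mean", "s_low", "s_high",
        "multiplier_mean", "multiplier_low", "multiplier_high",
    ]
    full = pd.concat([shocked[cols], zero[cols]], ignore_index=True)
    return full.sort_values(["region_id", "commodity_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# collapse-rate arithmetic and reporting
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DeclineSpec:
    """A cumulative population decline and its implied constant annual rate."""

    cumulative_decline: float
    n_periods: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.cumulative_decline < 1.0:
            raise ValueError("cumulative_decline must lie in [0, 1)")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")

    @property
    def annual_rate(self) -> float:
        return annual_decline_rate(self.cumulative_decline, self.n_periods)


def annual_decline_rate(cumulative_decline: float, n_periods: int) -> float:
    """Constant per-period rate producing the given cumulative decline.

    ``(1 - rate)^n = 1 - cumulative``; e.g. a 90% collapse over 14 years
    corresponds to 15.2%/year.
    """
    if not 0.0 <= cumulative_decline < 1.0:
        raise ValueError("cumulative_decline must lie in [0, 1); a 100% decline has no finite rate")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    return 1.0 - (1.0 - cumulative_decline) ** (1.0 / n_periods)


def shock_percent(s: float) -> float:
    """Report view of a fractional shock: percent, one decimal, half-up."""
    return round_half_up(100.0 * s, 1)
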