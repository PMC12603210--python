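# pollenomics

**What happens to food markets, welfare and nutrition if Europe's wild
pollinators collapse?**

`pollenomics` is a tested, reusable pipeline for simulating a hypothetical
collapse of wild pollinators confined to Europe. It is aimed at
ecological-economic modellers who want a transparent, fully scripted
implementation of the whole chain from pollination biology to market
outcomes:

1. **Shock engine** — crop-level pollination-dependence ratios `D_i`
   (fraction of yield attributable to animal pollination), wild-pollinator
   contribution shares `φ_c`, and production-value shares `shr_{c,i,n}` are
   combined into region×commodity productivity shocks

   `s_{c,n} = min(0.999, Σ_i shr_{c,i,n} · φ_c · D_i)`,

   with a 95% confidence interval obtained from triangular distributions
   over `(D_min, D_mean, D_max)` (±50% fallback when no interval data
   exist). The yield multiplier applied to the market model is `1 − s`.
2. **Market core** — a stylized multi-region partial-equilibrium model:
   constant-elasticity supply (with price-responsive yields and a land-supply
   elasticity), constant-elasticity demand, two-level CES Armington trade
   (domestic vs. imports with elasticity σ₁, across origins with σ₂), and
   ad-valorem price-transmission wedges. Calibrated in share form so the
   base year is an exact equilibrium; solved by damped fixed-point iteration
   on log prices.
3. **Welfare & nutrition** — exact decomposition into consumer surplus
   (Marshallian integral), producer surplus (area above the supply curve)
   and tariff revenue; per-capita kcal / vitamin A / folate availability by
   crop group and region bloc; back-of-envelope valuation calculators
   (household WTP extrapolation, managed-colony replacement cost).
4. **Experiment designs** — low/mean/high confidence-interval scenarios,
   a 3⁴ = 81-run full-factorial sensitivity grid, dependence-data-vintage
   comparison, and a population-weighted regression of parliamentary voting
   behavior on welfare exposure.

A seeded synthetic-data generator emulates the statistical shape of the real
input databases (right-skewed production values, balanced bilateral trade,
inelastic food demand, Europe holding ~10% of the world's
pollination-dependent production value), so every stage is testable offline.

## Worked example

```python
import pandas as pd
from pollenomics import compute_commodity_shock, annual_decline_rate
from pollenomics.shock import shock_percent

# rapeseed: a single crop fully defining its commodity account,
# dependence ratio 27.0%, wild-pollinator contribution 59.6%
shares = pd.DataFrame({"region_id": ["EU"], "commodity_id": ["Rapeseed"],
                       "crop_id": ["rapeseed"], "share": [1.0]})
dep = pd.DataFrame({"crop_id": ["rapeseed"], "D_mean": [0.270]})
phi = pd.DataFrame({"commodity_id": ["Rapeseed"], "phi": [0.596]})
out = compute_commodity_shock(shares, phi, dep)
print(shock_percent(out["s_mean"].iloc[0]))   # 16.1  (percent yield loss)
print(round(100 * annual_decline_rate(0.90, 14), 1))  # 15.2 (%/yr for a 90% collapse over 14 yrs)
```

Running the full analysis chain on the default synthetic world
(`python analysis/01_derive_shocks.py` … `05_vote_association.py`, default
seed 42) prints, among other things:

```
Mechanisms on the European dependent aggregate: yield -28.8% > production
-27.4% decline (land/price buffering), producer prices +10.8% (inelastic
demand overshoot).
World: total welfare -12,364,900 < 0 while producer surplus 9,637,830 > 0 —
the King-Davenant pattern under inelastic demand.
completed 81 model runs (4 factors x 3 levels)
```

i.e. European producer prices overshoot the yield loss, cropland expands
(+0.6% in Europe on this seed), world welfare falls while world producers
gain, and micronutrient availability drops faster than calories because the
shocked vegetable/fruit group is nutrient-dense but calorie-light. Units on
the synthetic fixture are thousand EUR (quantities in kt × prices in EUR/t);
only the qualitative mechanisms, not the magnitudes, are comparable to a
full-scale model calibration.

There is also a CLI for running the stages from the shell; see
`pollenomics --help` (`synthesize-data`, `derive-shocks`, `simulate`,
`sensitivity`, `associate`, `report`).

## Layout

```
src/pollenomics/     library: shock, market, welfare, nutrition,
                     sensitivity, synthetic, config, cli
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      model description, assumptions and limitations
```
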