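# Methods

This note documents the model, its assumptions, the defaults, and what the
synthetic fixture can and cannot show.

## 1. Productivity shocks

A commodity account `c` in region `n` receives the shock

```
s_{c,n} = min(cap, Σ_i shr_{c,i,n} · φ_c · D_i),     cap = 0.999
```

- `D_i ∈ [0,1]` — dependence ratio of crop `i`: the fraction of its yield
  attributable to animal-mediated pollination (managed + wild).
- `φ_c ∈ [0,1]` — share of that pollination service delivered by *wild*
  pollinators. Where crop-specific measurements are missing the cross-crop
  average is imputed and flagged.
- `shr_{c,i,n}` — the crop's share in the commodity's base-year production
  value, normalized to 1 per (region, commodity).

The **yield multiplier** passed to the market model is `m = 1 − s`. The two
quantities are carried as separate, explicitly named fields: the multiplier
equals 1 at zero dependence, while report tables print the shock `s`. Fully
dependent crops (`D = 1`, `φ = 1`) are capped at a 99.9% shock so yields
never reach exactly zero. Shocks apply to European regions only;
extra-European regions carry `s = 0` by construction.

**Confidence bounds.** `D_i` is treated as triangular on
`(D_min, D_mean, D_max)` with the mode at `D_mean` — the simplest
distribution consistent with the three reported statistics. The 95% band
replaces each crop's ratio by its 2.5%/97.5% triangular quantiles and
re-aggregates with the mean formula, every crop at the same quantile
(comonotone aggregation). This matches a presentation of a single
low/mean/high scenario triple rather than a convolution of independent crop
uncertainties; it is conservative (widest) for positively dependent crops.
Crops with no interval data fall back to ±50% of their mean contribution.
As coverage → 0 both bounds collapse onto the triangular *median*, which
coincides with the mean shock for symmetric intervals.

**Collapse rate.** A cumulative decline `L` over `T` periods implies the
constant annual rate `1 − (1 − L)^{1/T}`; the default horizon is 14 annual
periods (base year through 2030), under which a 90% collapse corresponds to
15.2%/year.

**Rounding.** Fractions internally; percent formatting (one decimal,
half-up so 7.95 → 8.0) only at the reporting boundary. Report columns are
suffixed `_pct` to prevent double scaling.

## 2. Market model

A stylized multi-region partial-equilibrium model of the agri-food sector:
incomes and all non-agricultural prices are exogenous, markets clear in
physical terms, and two steady states (reference vs. collapse) are
compared — no transition path. All functional forms are constant-elasticity,
written in calibrated share form so the observed base year is an exact
equilibrium with the base-year value shares as CES weights (calibration is
closed-form and its residual is reported; a zero-shock solve returns the
baseline bit-for-bit up to solver tolerance).

Per region `n` and commodity `c`, with price ratio `r = p/p0`:

| block | form |
|---|---|
| supply | `Q = Q0 · m · r^{ε_s} · R̄^{λ}` |
| realized yield | `y = y0 · m · r^{η}` |
| area (derived) | `A = Q/y = A0 · r^{ε_s−η} · R̄^{λ}` |
| demand | `X = X0 · (P_C/P_C0)^{ε_d}`, `ε_d < 0` |
| trade | two-level CES: domestic vs. import composite (σ₁), origins (σ₂) |
| price link | landed = origin · (1 + τ); wedge revenue to destination government |

`R̄_n = Σ_c a0_{n,c} · m_c r_c^{1+η}` is the region's area-weighted
per-hectare return index (1 in the base year); its elasticity `λ` governs
total cropland expansion. Design choices worth flagging:

- `ε_s` is the *total* own-price supply elasticity: this keeps the
  closed-market oracle `p* = (1/m)^{1/(ε_s+|ε_d|)}` exact and makes the
  one-market examples verifiable by hand. The area equation is the implied
  residual (`ε_s − η` on price), not a separate behavioral parameter.
- The exogenous shock `m` shifts supply one-for-one at fixed prices (a 10%
  yield shock cuts supply exactly 10% before any price response); it is
  excluded from the return index exponent so the pass-through example stays
  exact, but included in its level so collapsing yields depress measured
  returns.
- `η > 0` collapses technology-intensity switching into a single
  price-responsive yield term; `λ > 0` makes aggregate cropland expand when
  returns rise. Both buffers are data, not code: defaults `η = 0.2`,
  `λ = 0.1` (modest, in line with long-run land-supply estimates), all
  other elasticities drawn per region×commodity by the generator.
- Ad-valorem wedges only (`τ ≥ 0`); wedges cancel in price *ratios*, so the
  Armington share form needs no wedge levels beyond calibration.
- Managed pollinators are held fixed (zero substitution elasticity); no
  processing/feed layers, no quotas, no income feedback.

**Solver.** Damped diagonal quasi-Newton tatonnement on log producer
prices: `Δln p = damping · ln(demand/supply) / J` with `J = ε_s + |ε_d| +
max σ` as the slope guess. Convergence criterion is the largest relative
market-clearing residual ≤ 1e-6 (tighter than the price-change criterion it
implies); cap 500 iterations, damping 0.5. The default 6×6 fixture solves
in ~100–200 iterations; non-convergence raises an error carrying the full
residual trajectory rather than returning a partial state. The solve is
pure deterministic NumPy — identical inputs give bit-identical states.

## 3. Welfare accounting

Per region, summed over commodities:

- **ΔCS** `= −∫_{P0}^{P1} X0 (P/P0)^{ε_d} dP` under the composite consumer
  price index (log form at `ε_d = −1`). With no income effects in a
  partial-equilibrium demand curve this Marshallian measure coincides with
  the compensating-income definition.
- **ΔPS** `= Δ[pQ/(1+ε_s)]` — exact for the constant-elasticity supply
  curve; the `λ` cross-term (regional return index) is treated as part of
  the curve's level, so with `λ > 0` the measure is exact conditional on
  the equilibrium return index. Processing margins are folded into producer
  surplus (there is no separate processing sector).
- **ΔGov** `= Δ Σ τ · p_origin · imports` by destination.

The total is the exact component sum, so adding-up holds to machine
precision at every aggregation level. Because the Marshallian CS *level* of
an inelastic constant-elasticity demand diverges, the "share of baseline
welfare" denominator is a proxy: base consumer expenditure + base producer
surplus + base tariff revenue. The valuation calculators (WTP × households;
colonies × unit cost, optionally per hectare) are pure arithmetic;
per-hectare denominators are user inputs.

## 4. Nutrition

Availability per nutrient = `Σ_c q_c κ_c / population / 365` with exogenous
coefficients `κ` per product ton (kcal, vitamin A, folate; units carried as
opaque labels). Reports are percent changes by crop group and bloc;
population cancels. This is *availability*, not intake net of waste, and no
health outcomes are modelled.

## 5. Experiment designs

- **CI scenarios:** independent solves at `s_low / s_mean / s_high` with
  min/mean/max envelopes per indicator; any non-converged member fails the
  whole run.
- **Sensitivity grid:** full factorial over four factors — wild
  contribution, dependence ratio, supply elasticity, trade elasticity (σ₁
  and σ₂ scaled jointly as one block) — at multiplicative levels
  `{0.5, 1.0, 1.5}` (central level is the core scenario; values above 1 are
  clipped so ratios stay in [0,1]). The exact published level values are
  not public; symmetric multiplicative levels are the documented,
  overridable default. 3⁴ = 81 runs, summarized by median/IQR/min/max.
- **Source comparison:** identical pipeline with the dependence table
  swapped (e.g., an older vintage with mostly lower ratios); headline
  output is the relative change in the welfare loss.
- **Vote association:** population-weighted least squares of rejection
  shares on consumer-welfare change (share of GDP), per proposal and for
  their average; descriptive only, no causal claim.

## 6. Synthetic data

The generator emulates the *shape* of the real input databases: ~40-region
world collapsed to 6 regions (2 EU + 1 other-European + 3 extra-European)
× 6 commodities (3 pollination-dependent) by default, so the whole pipeline
including the 81-run grid completes in seconds; region counts are
configurable and doubling them preserves all invariants. Features emulated:

- right-skewed (log-normal) production values and region sizes;
- dependence ratios in [0,1] with ordered min/mean/max, one crop without
  interval data (fallback path), an optional fraction of fully dependent
  crops (cap path), and a mostly-lower alternative vintage;
- multi-crop commodities exercising value-share aggregation;
- bilateral trade built from import-penetration rates and origin weights
  (intra-bloc biased), then **extra-European demand rescaled by an exact
  linear solve so Europe holds exactly the configured share (default 10%)
  of the world's pollination-dependent production value** — every flow is
  linear in destination demand, so the factor has a closed form;
- world trade balanced by construction (production ≡ domestic use +
  exports);
- inelastic demand (`ε_d ∈ (−0.8, −0.2)`), supply elasticities in
  (0.3, 0.8), σ₁ ∈ (2, 4), σ₂ ∈ (4, 8), wedges in (0, 0.2);
- nutrient coefficients with vitamin A and folate concentrated in (and
  calories diluted in) vegetables/fruits, so micronutrient availability
  falls faster than calories under the shock, as with real nutrient-dense
  crops.

All randomness flows through one integer-seeded `numpy` generator, so
datasets are identical across platforms for a given config.

**What the fixture does not show.** It makes no attempt to match real
country totals, the 273-region European supply resolution, or the published
monetary magnitudes; those require the full-scale model database. Passing
tests demonstrate the *mechanisms* — price overshoot under inelastic
demand, King-Davenant producer gains, trade buffering, cropland expansion,
intensification, micronutrient concentration — not the published numbers,
which is why the acceptance checks on the market model are property-based.

## 7. Numerical conventions and degenerate inputs

- Triangular quantile/CDF via `scipy.stats.triang`, with the degenerate
  point mass `a = b` handled explicitly; closed forms serve as test
  oracles.
- CES indices use the log (Cobb–Douglas) limit at σ = 1 and return 1 for
  empty nests (autarkic destinations).
- Zero-value region-commodity cells are dropped (with a warning) in value
  -share mapping; zero denominators in trade indicators yield NaN flagged
  `defined = False`, never silent zeros.
- Weighted regression via `statsmodels` WLS; hand-solved normal equations
  are the test oracle.
- Config validation via pydantic (unknown keys rejected by name); results
  are staged to a temporary directory and renamed into place so partial
  failures leave nothing behind; manifests record SHA-256 digests, config
  hash and seed.

## 8. Known limitations

- Constant-elasticity forms cannot capture corner solutions (crop exit,
  binding quotas) or the cost-function detail of a programming-based supply
  model; magnitudes are illustrative.
- Comonotone bounds ignore cross-crop dependence-uncertainty correlation
  structure by assumption (single low/mean/high triple).
- ΔPS omits harvest-cost changes from lower per-hectare yields; producer
  gains should be read with the same caution as in any yield-shock PE
  exercise.
- The vote association is a descriptive cross-sectional regression on few
  observations; no confounders, no causality.
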