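# Methods

## Model overview

`luces` couples a raster landscape to two populations of decision agents and
an annual ecosystem-service account. The landscape is a dense grid of square
plots (default 100 × 100 cells of 0.5 ha, a 5 000-ha window) in which each
cell carries a land-cover class (peat forest, mineral forest, agroforest,
timber plantation, oil-palm plantation, agriculture, settlement, degraded
land), an immutable soil class (peat/mineral), per-commodity suitability
scores in [0, 1], an optional concession-zone id, an owner, years since last
conversion, and cumulative peat-carbon depletion. A simulated district the
size of the presets (8 000–17 000 km²) cannot be tiled by this window; a run
is therefore interpreted as a representative window, and district-scale
totals require rescaling `cell_area_ha`.

### The annual cycle

Each year executes twelve steps in a fixed order: (1) scenario price
adjustment, (2) market-expectation update, (3) demography, (4–5) company
decisions and conversions, (6–7) household decisions and conversions, (8)
NTFP collection and harvests, (9) income realisation and expectation update,
(10) ageing and peat oxidation, (11) settlement redistribution, (12)
ecosystem-service accounting. Companies act before households: planned
conversion (permits, quotas) precedes unplanned smallholder response. The
ordering is a design choice of this package — fixed to make runs
reproducible — and is the main structural assumption a user should be aware
of; results were not found to be sensitive to swapping steps 4–5 and 6–7 in
exploratory runs, but no systematic sensitivity analysis ships with the
package.

### Decision models

The decision rules are deliberately minimal and fully config-exposed,
reproducing three stated influences on household behaviour — price
expectations, market knowledge and preferences — without claiming any
particular econometric form:

* **Adaptive expectations.** `E_t = (1 − α)·E_{t−1} + α·realized_t`, with
  `α = 0.5` by default. Realized income of an option is
  `(yield · farm-gate price − production cost) · workable ha`, where
  workable area is household labour divided by the option's labour cost.
  Negative incomes are carried (options may be unattractive) and clamped at
  zero only inside choice weights.
* **Household choice.** One option per household-year is drawn with
  probability `P(i) ∝ pref_i · exp(β·max(E_i,0)/s)` over the feasible set
  (default preferences are uniform). `s = 100` currency units/yr sets the
  income scale; `β = 2` is the choice sharpness. β was fixed, together with
  the default economics, so that a 15 % price premium on forest-friendly
  commodities produces a visible (not winner-take-all) shift of choice mass
  — the regime the scenario narrative describes, in which premium prices
  lift NTFP and agroforest incomes to the level of oil palm. At `β → 0`
  choices ignore income; at large β the model degenerates to argmax.
  A chosen convert option claims the candidate cell with the highest
  suitability (ties broken in row-major order); at most one conversion per
  household-year by default.
* **Company expansion.** Candidate cells (inside the permit zone, unowned,
  permitted by the scenario) are ranked by suitability × profit margin with
  deterministic row-major tie-breaks and converted up to an annual quota,
  default 2 % of the zone area per year — chosen to spread expansion over
  the 15-year horizon. Profit margins default to 300 (oil palm) and 150
  (timber) currency/ha/yr.
* **Demography.** Household count grows as `floor(n·(1+g))` per year (floor
  keeps small-n runs deterministic); new households are placed on uniformly
  drawn settlement cells and inherit default preferences.

### Policy scenarios

Scenarios are data, not code: a moratorium window (start/end year), the
actor kinds in scope (default companies only), the protected cover classes
(default peat forest), the soils open to new company plantations, a premium
commodity set with price-premium and cost-subsidy fractions, and a community
logging switch. The shipped presets are BAU (window 2011–2014), EM (window
2011–2036, mineral-soil-only company plantations) and MPL (EM plus +15 %
prices / −5 % costs on rattan, jelutong, rubber and community timber, and a
community-logging ban). The premium is applied as exact multiplicative
factors 1.15 and 0.95. The logging ban is modelled as a hard feasibility
exclusion rather than a probabilistic detection process — the simplest
reading of "improved monitoring"; a detection-probability hook would slot
into the same rule. The permission predicate returns a reason code
(`moratorium`, `company_soil_restriction`, `community_logging_banned`) so
simulation logs can be audited rule by rule.

### Ecosystem services and carbon

Cultivated services (rubber, rice, oil palm, plantation timber) are summed
over mature cells of the producing class (maturity lags: agroforest 2 yr,
agriculture 1 yr, oil palm 3 yr, timber plantation 5 yr). NTFPs (rattan,
jelutong) are credited only for forest cells actually visited by collect
actions, so an NTFP premium raises supply *and* forest retention through the
same mechanism. Carbon is above-ground biomass per class plus a peat stock
(default 3 000 t CO₂e/ha) under peat soil that oxidises at 60 t CO₂e/ha/yr
once the cell is under non-forest cover, floored at zero. Annual emission
uses a **gross** convention — the sum of positive per-cell stock decreases
(conversion losses plus peat oxidation) — with above-ground gains reported
separately as sequestration and never netted. Gross was chosen because no
single net formula reconciles stock trajectories with an annual-emission
column across scenarios; the convention is explicit in the account fields.
Emission reduction between scenarios is
`100·(Σ baseline − Σ alternative)/Σ baseline` over equal-length ledgers.

### Parameter defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| cell area | 0.5 | ha | standard plot size for this model family |
| grid | 100 × 100 | cells | study-scale window; config-adjustable |
| horizon | 2010 → 2025 | yr | 15-year policy horizon |
| α (expectation smoothing) | 0.5 | — | equal weight on memory and news |
| β (choice sharpness) | 2.0 | — | premium shifts choices visibly, see above |
| s (income scale) | 100 | currency/yr | order of per-option income spread |
| search radius | 8 | cells | ~4 km neighbourhood at 0.5-ha plots |
| household labour | 2.0 | units/yr | works ~1 ha per option at default costs |
| company quota | 2 % | of zone/yr | multi-year expansion trajectory |
| settlement threshold / radius | 5 / 5 | conversions / cells | a new settlement follows clustered land demand |
| peat stock / oxidation | 3000 / 60 | t CO₂e/ha, /ha/yr | tropical-peat order of magnitude |

Economics defaults (editable CSV `src/luces/data/economics.csv`) place
smallholder net incomes at roughly: oil palm 580, rattan 510, rubber 500,
jelutong 490, community timber 460, paddy 405 currency/household/yr. They
are *placeholders with a designed ordering* — oil palm on top by less than
15 % — not a calibration: under the MPL premium, rattan (592) and rubber
(583) overtake oil palm, which is the qualitative regime the livelihood
scenario explores. All coefficient tables are flagged uncalibrated.

## Synthetic district generator

The generator emulates the two study-district profiles: `west_kotawaringin`
(52 % forest, 40 % of it on peat, 4.2 %/yr population growth, 15 % of
non-settlement land under concession) and `kapuas` (74 % forest, 60 % on
peat, 0.7 %/yr growth, 10 % concession, and a larger drained-peat fringe
reflecting its land-use history). Class areas are allocated by largest
remainder (exact to one cell), then placed by competitive seeded region
growing; `clumping` sets the target patch size (`1 + 10·clumping` cells),
with `clumping = 0` degenerating to a spatially random map. Settlements form
`n_settlement_seeds` clusters; concessions are grown as two contiguous
blocks by single-seed frontier BFS; peat soil extends outward from the peat
forest by taxicab distance; suitability surfaces are smoothed uniform noise.
The generator is a pure function of (profile, dims).

What it does **not** emulate: road networks and market access gradients,
rivers and coasts, real settlement geography, tenure mosaics, and the actual
spatial covariance of peat domes with concessions. Tests passing on
synthetic districts therefore demonstrate the mechanics and invariants of
the model — determinism, conservation, policy-rule compliance, accounting
identities, directional scenario ordering — not predictive skill on real
maps, which would require the original GIS inputs and a calibration that are
out of scope here.

## Numerical and degenerate-case choices

* All stochastic draws flow through one `numpy` PCG64 generator seeded from
  the config; runs are bit-reproducible and the suite asserts it.
* Ties in cell ranking always break in row-major (row, col) order.
* Choice weights subtract the maximum exponent before `exp` (overflow-safe;
  cancels exactly in normalisation to well below the 1e-12 test tolerance).
* Empty feasible sets return empty action lists, never errors; zero-labour
  households act as absent.
* Fraction-to-count allocation uses largest remainder, so requested and
  realized class fractions differ by at most one cell per class.
* NODATA is rejected on raster read: the window must be fully observed.
* Settlement is an absorbing class; soil never changes; peat stock is
  non-increasing (no peat formation on this horizon); forest regrowth is
  not modelled over the 15-year horizon.

## Known limitations

* Decision equations are this package's own minimal forms; no labour or land
  markets, migration, credit, or inter-agent negotiation.
* One conversion per household-year bounds smallholder clearing rates.
* The emission account ignores fire and peat-subsidence hydrology.
* Backcasting against real 2005/2010 maps — and hence published similarity
  percentages — requires data not shipped here; the harness runs on any
  user-supplied ESRI ASCII map pair.
* Scenario outputs are orderings and sensitivities under placeholder
  economics, not calibrated district totals.
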