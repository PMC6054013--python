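# luces

An agent-based simulator of land-use change and ecosystem-service supply at
tropical forest margins, built for *ex ante* comparison of forest-moratorium
policy scenarios on Indonesian peatland districts.

Deforestation at forest margins is driven by two very different actor kinds:
permit-holding plantation **companies** (planned conversion inside concession
zones) and local **households** (unplanned conversion driven by expected
income from livelihood options such as NTFP collection, rubber agroforest,
paddy, smallholder oil palm and community timber). A moratorium on company
conversion of peat forest constrains only the first group; whether it reduces
landscape-scale carbon emissions depends on how households respond. `luces`
simulates both groups on a raster landscape (default 100 × 100 plots of
0.5 ha) through an annual 12-step cycle and accounts, each year, for six
provisioning services and for above-ground and peat carbon stocks and
emissions.

## Model core

* **Company decisions.** Each company ranks the permitted cells of its
  concession by suitability × profit margin and converts the best cells up
  to an annual quota, subject to the scenario rules.
* **Household decisions.** Each household holds adaptive income expectations
  `E_t = (1 − α)·E_{t−1} + α·realized_t` per livelihood option and draws one
  option per year from a preference-weighted logit,
  `P(i) ∝ pref_i · exp(β·max(E_i, 0)/s)`, over the options feasible near its
  home. Collection options never change land cover.
* **Policy scenarios** (shipped presets):
  * `BAU` — company-scale peat-forest moratorium 2011–2014; households
    unaffected.
  * `EM` — moratorium extended to 2011–2036; new company plantations only on
    mineral soil.
  * `MPL` — EM plus a livelihoods programme: +15 % farm-gate prices and a
    5 % cost subsidy for rattan, jelutong, agroforest rubber and community
    timber, and strict enforcement against community logging.
* **Carbon.** Above-ground stock per class plus a peat stock under peat
  soils that oxidises at a fixed rate once the cell is converted. Annual
  emission is the gross sum of positive per-cell stock decreases;
  sequestration is reported separately.

Two synthetic district presets (`west_kotawaringin`, 52 % forest and 4.2 %/yr
population growth; `kapuas`, 74 % forest and 0.7 %/yr) let every experiment
run without external data; user-supplied ESRI ASCII rasters are also
accepted.

## Worked example

```python
from luces import SimulationConfig, run_simulation, emission_reduction

bau = run_simulation(SimulationConfig(scenario="BAU", district="west_kotawaringin", seed=1))
mpl = run_simulation(SimulationConfig(scenario="MPL", district="west_kotawaringin", seed=1))

for name, res in [("BAU", bau), ("MPL", mpl)]:
    last = res.areas.iloc[-1]
    forest = last["peat_forest"] + last["mineral_forest"]
    emis = sum(a.annual_emission for a in res.ledger)
    print(f"{name}: forest 2010 = {res.areas.iloc[0][['peat_forest','mineral_forest']].sum():.3f}, "
          f"forest 2025 = {forest:.3f}, cumulative emission = {emis:,.0f} t CO2e")
print(f"MPL vs BAU emission reduction: {emission_reduction(bau.ledger, mpl.ledger):.1f} %")
```

prints

```
BAU: forest 2010 = 0.520, forest 2025 = 0.381, cumulative emission = 659,920 t CO2e
MPL: forest 2010 = 0.520, forest 2025 = 0.395, cumulative emission = 548,905 t CO2e
MPL vs BAU emission reduction: 16.8 %
```

Under business as usual this window loses 14 points of forest cover over
15 years; the livelihoods package keeps household choice mass on collection
and agroforest options, retaining more forest and cutting cumulative
emissions by about a sixth on this seed. `res.areas` is the year × class
fraction table, `res.ledger` the annual ecosystem-service and carbon ledger,
and `res.action_log` the audited list of every agent action.

The same runs are available from a shell:

```bash
luces run --scenario MPL --district west_kotawaringin --seed 1 --years 15 --out out/
luces validate --start lc2005.asc --reference lc2010.asc --reference-year 2010 --seeds 20 --out val/
```

`luces validate` backcasts from a historical map and reports percent
agreement (plus a confusion matrix and kappa) between simulated and observed
maps.

## Caveats

The default economics and ecosystem-service coefficients are uncalibrated
order-of-magnitude placeholders (editable CSVs in `src/luces/data/`); the
simulator is a scenario-comparison tool, and its outputs should be read as
orderings and sensitivities, not as calibrated district totals. See
`docs/methods.md` for the full model description, parameter defaults and
limitations.
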