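# hrcimpact

Health impact assessment of regulating **health-related claims (HRCs)**
— the nutrition and health statements printed on pre-packaged food —
with a **nutrient profile model**.

Regulators propose letting foods carry claims only if they pass a
nutrient profile model (an algorithm classifying foods as healthier or
less healthy from their composition). The catch: claim-carrying foods
are already, on average, *healthier* than foods without claims, and
claims boost sales. Stripping claims from foods that fail a profile
model can therefore push purchases towards *less* healthy products,
while a world in which manufacturers reformulate failing foods to keep
their claims improves diets. This package quantifies both outcomes, in
diet terms and in deaths averted, for a UK-scale population.

It is written for epidemiologists and policy modellers: a Python
library first (see `examples/`), with a thin `hrcimpact` CLI over the
same functions.

## The model

Per Eatwell Guide food group *g* (six guide groups plus composite and
miscellaneous foods):

* claim prevalence *q* and a choice odds ratio *OR* give the claim
  foods' share of sales on the odds scale,
  `s = q·OR / (q·OR + (1 − q))`;
* per-nutrient **nutrient quality ratios**
  `NQR(n) = mean claim-food content / mean non-claim content` (per
  100 g) split each group's surveyed intake `T(n)` into the two
  streams via `c_non(n) = 100·T(n) / (S_hrc·NQR(n) + S_non)`,
  `c_hrc = NQR·c_non`, conserving the surveyed totals exactly.

Counterfactuals (group sales totals fixed; substitution stays within a
group):

* **restricted** (models 1a FSANZ NPSC / 2a EU-style): prevalence drops
  to the pass-prevalence, the split is re-solved with baseline ORs, and
  the surviving claim stream takes the pass-subset NQRs; foods losing
  claims merge into the non-claim stream at baseline non-claim
  composition;
* **reformulated** (1b / 2b): prevalence and split stay at baseline;
  the claim stream's composition moves to the pass-subset NQRs.

Diet deltas feed a population-impact-fraction engine: each exposure has
a truncated-normal population distribution (mean from purchases, SD
from diet surveys); relative risks act per exposure unit, directly or
through body-mass index, systolic blood pressure or blood cholesterol;
`PIF = (Σ P·RR − Σ P′·RR) / Σ P·RR` per cause, factors combining as
`1 − Π(1 − PIF)`, scaled by stratified baseline mortality. Monte Carlo
resampling of prevalences (logit-normal), ORs, NQRs and RRs
(lognormal) yields 95% uncertainty intervals and a tornado
decomposition.

All study inputs (product-label survey, purchase/intake tables,
population and mortality strata) are generated synthetically with the
statistical structure the analysis assumes; the epidemiological
relative risks are illustrative configuration values, not a published
catalogue.

## Worked example

```python
import hrcimpact as h

cfg = h.study_calibrated_config()
base = h.baseline_from_config(cfg)
print(f"claim foods: {100*base.hrc_purchase_share():.1f}% of purchases, "
      f"{100*base.hrc_energy_share():.1f}% of energy")

for model in ("1a", "1b"):
    delta = h.diet_delta(h.run_scenario(cfg, model, baseline=base), base)
    deaths = h.deaths_averted(delta, cfg)
    print(f"model {model}: energy {delta['energy_kcal']:+.1f} kcal/d, "
          f"{deaths.total:+.0f} deaths averted "
          f"({deaths.total_with_energy:+.0f} with energy)")
```

prints

```
claim foods: 38.2% of purchases, 29.2% of energy
model 1a: energy +8.6 kcal/d, -117 deaths averted (-392 with energy)
model 1b: energy -87.4 kcal/d, +3233 deaths averted (+5912 with energy)
```

Claim foods supply ~38% of purchase grams but only ~29% of energy —
they are less energy-dense. Restricting claims (1a) *raises* energy
intake and costs lives (negative deaths averted); reformulation (1b)
lowers energy intake by ~87 kcal/person/day and averts thousands of
deaths per year at UK population scale. `examples/` walks every stage:
survey generation, profile scoring, disaggregation, scenarios,
mortality impact, uncertainty.

The same pipeline is reachable from the shell:

```bash
hrcimpact baseline
hrcimpact scenario --model 1b
hrcimpact mc --model 1a --n-iter 10000 --tornado
```

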