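# Methods

## Scope and structure

`hrcimpact` models the population-health consequences of regulating
health-related claims (HRCs) on pre-packaged food with a nutrient
profile model. The pipeline has five stages, each an importable module:

1. **synthetic** — generates every study input (product-label survey,
   purchase/intake tables, intake SDs, population and mortality
   strata);
2. **profiling** — scores foods against a points-based profiling
   criterion (FSANZ-NPSC-style) and a configurable threshold model
   (EU-style) to derive claim-eligibility pass prevalences and
   pass-subset nutrient quality ratios;
3. **disaggregate** — splits group-level purchases into claim and
   non-claim streams;
4. **scenarios** — builds restricted and reformulated counterfactual
   diets and their deltas;
5. **prime** + **uncertainty** — converts deltas into deaths averted
   via population impact fractions, with Monte Carlo uncertainty and a
   tornado decomposition.

## Disaggregation model

For each food group the purchase survey supplies one sales total
`T_g` (g/person/day) and one nutrient intake vector. Three parameters
divide these between claim and non-claim streams:

* prevalence `q` — share of available products carrying a claim;
* choice odds ratio `OR` — odds of choosing a product when a claim is
  present relative to when it is not;
* nutrient quality ratios `NQR(n)` — claim-food mean content per 100 g
  divided by the non-claim mean.

The OR is applied **on the odds scale**: among purchases the odds of an
item carrying a claim are `OR` times the availability odds, so the
claim sales share is `s = q·OR / (q·OR + 1 − q)`. This is the only
reading consistent with a choice-experiment odds ratio plus
conservation of total sales, and it is isolated in `hrc_sales_share`
so a probability-scale reading would be a one-function swap. A
discrete-choice simulation oracle (multinomial choice over a synthetic
shelf with weight `OR` on claim items) validates the closed form in the
test suite.

The non-claim concentration then solves the conservation constraint
`c_non(n) = 100·T(n) / (s·T_g·NQR(n) + (1−s)·T_g)`, with
`c_hrc = NQR·c_non`; reconstruction of the input totals is exact up to
float rounding (tested at 1e-9 relative over random configurations).
Fruit and vegetables are carried through the same algebra as food
quantities (grams of fruit / vegetables per 100 g of group purchases),
non-zero only in the fruit-and-veg group.

## Scenarios

* **Restricted**: prevalence drops to the claim-and-pass prevalence,
  the split is re-solved with *baseline* ORs (the published table
  prints a single OR column), the claim stream takes the pass-subset
  NQRs, and the non-claim concentration is held at its baseline value.
  Foods losing claims thereby merge into the non-claim stream at the
  baseline non-claim composition — which may understate that stream's
  quality, since the foods joining it tend to be healthier; this
  limitation is inherited from the modelled assumption, not resolved.
* **Reformulated**: the sales split stays at baseline; only the claim
  stream's composition moves to the pass-subset NQRs.
* **Uniform boost sensitivity**: per-group ORs are replaced by the OR
  implied by a uniform relative sales lift `b` for claim foods,
  `OR = (1+b)(1−q)/(1−(1+b)q)` (default `b = 0.16`, the natural-
  experiment estimate), applied in both arms including the
  miscellaneous group.

Group sales totals never change across scenarios (substitution is
within-group); the change in total nutrient intake is the measured
outcome, so intake is deliberately *not* conserved between scenarios.

## Impact engine

Each dietary exposure has a truncated-at-zero normal population
distribution: mean from the purchase data, SD from diet-survey
defaults. A counterfactual shifts the mean by the scenario delta and
keeps the SD. Relative risks apply multiplicatively per unit of
exposure, or per unit of a mediator for mediated links (mediator change
= slope × exposure change); mediators carry their own population
distributions (BMI 27 ± 4.5 kg/m², SBP 125 ± 15 mmHg, total cholesterol
5.1 ± 1.0 mmol/L). The population impact fraction per link is
`(Σ P·RR − Σ P′·RR)/Σ P·RR` on a 1000-point grid spanning mean ± 6 SD
(truncated at zero; agreement with a 10,000-point grid is tested).
RR curves are anchored at the baseline mean, though the PIF is
invariant to that reference. Links acting on one cause combine as
`1 − Π(1 − PIF)`; per-risk-factor report rows are computed with each
factor alone, so they intentionally do not sum to the combined total.
Energy is routed solely through the BMI mediator and reported as a
separate energy-inclusive total.

The RR catalogue is **illustrative configuration**: literature-scale
magnitudes (e.g. fruit RR 0.95 per 80 g/day for ischaemic heart
disease; satfat 0.02 mmol/L cholesterol per g/day with RR 1.9 per
mmol/L) chosen to give plausible relative pathway strengths, not a
reproduction of any published meta-analysis set. Causes are ischaemic
heart disease, stroke, colorectal and stomach cancer, grouped into
CVD/cancer for reporting.

## Parameter tables and editorial choices

The per-group claim parameters reproduce the published table of choice
ORs and prevalences, with three documented repairs:

* the starchy-carbohydrates OR row prints a CI that excludes its point
  estimate (it duplicates the pooled OR's CI); the packaged default
  rebuilds the CI around 1.17 using the pooled OR's relative log-width
  → (1.07, 1.28);
* the oils-and-spreads group is absent from the published table and is
  filled with the pooled OR 1.75 (1.60, 1.91) and overall prevalence
  26% (24–28%), with illustrative pass prevalences;
* the table's three prevalence columns are not unambiguously labelled.
  `default_config()` reads them as (baseline, FSANZ-pass, EU-pass).
  `study_calibrated_config()` uses the reverse reading
  (FSANZ-pass, EU-pass, baseline), which is the only one under which
  every restricted prevalence is at or below baseline — matching the
  stated ~10-point restricted reduction — and under which the baseline
  claim purchase share lands at ~37–38%. Column order is a config
  option either way, and restricted builds reject pass > baseline
  unless explicitly allowed.

Calibrated sales/intake rows distribute the published daily totals
(1906.8 kcal, 66.1 g protein, …, 151.2 g fruit, 131.1 g vegetables)
across groups in realistic proportions. Baseline NQRs follow the
label-survey aggregates (claim foods −43.7 kcal, −2.9 g satfat,
−3.2 g sugars, −354 mg sodium, +0.7 g fibre per 100 g), giving e.g.
energy NQR 0.70; pass-subset NQRs reflect the wider claim-and-pass gap
(energy 0.59 FSANZ / 0.64 EU). NQR relative SEs (0.18 baseline, 0.22
pass variants) mirror the small label-survey samples, the dominant
uncertainty source. Sodium↔salt conversion is fixed at
salt = 2.5 × sodium.

## Synthetic data generator

Products are drawn per group: Bernoulli claim flags at the group
prevalence; per-nutrient truncated-at-zero normals (relative SD 0.40)
with claim means shifted by the aggregate claim/non-claim differences,
floored at 10% of the non-claim mean where a shift would go negative.
Truncation resamples rather than clips, so means stay interpretable;
nutrients are drawn independently because only marginal moments are
available — real label data are correlated (energy with fat and
sugars), so covariance-sensitive conclusions should not be read off the
generator. Population (44 M adults, 25+ in 5-year bands) and mortality
(Gompertz-like age gradient over 125,000 annual deaths across four
causes) are deterministic UK-scale restatements of config totals.
Passing tests therefore demonstrate internal consistency of the method
under the assumed structure, not agreement with real LCF/NDNS/ONS
records, which the package never ingests.

## Uncertainty analysis

Per iteration one full parameter bundle is drawn — ORs and RRs
lognormal with `σ = ln(hi/lo)/3.92`, prevalences logit-normal matched
to their CIs, NQRs lognormal with `σ = √ln(1+(se/nqr)²)` — and shared
by baseline and counterfactual (common random numbers; without this the
deltas would be noise-dominated). Draws are reproducible per
(seed, iteration) via seeded generators; parameters are drawn
independently of each other (no correlation information exists).
Point estimates come from central parameters; 95% uncertainty
intervals are the 2.5/97.5 percentiles. The tornado varies one
parameter group at a time with the others held at central values.
The reference iteration count is 10,000; tests and the examples use
200–2,000 iterations, a package choice that leaves percentile estimates
well inside the qualitative conclusions.

## Nutrient profile scoring

The points-based criterion encodes the published structure: baseline
points (0–10 each, strict "greater-than" bands) for energy (335 kJ
steps), saturated fat (1 g), total sugars (4.5 g) and sodium (90 mg);
modifying points for fruit/veg/nut/legume content (1/2/5 at
>40/60/80%), protein (1.6 g steps, max 5) and fibre (0.9–4.7 g bands,
max 5); protein points are withheld when baseline ≥ 13 unless FVNL
points ≥ 5; pass thresholds are score < 1 (beverages), < 4 (foods),
< 28 (fats/oils). Band tables are packaged data and overridable — they
are a faithful structural encoding for modelling, not a legal
reproduction of the regulatory schedule, and claim-type-specific
eligibility rules are out of scope. The EU-style model is a per-group
cap table (energy/satfat/sugars/sodium per 100 g), explicitly
non-authoritative since the draft model's true structure is not public
here. An independent table-lookup oracle in the test suite checks the
scorer on 1,000 random compositions.

## Known limitations

* No cross-category substitution or compensatory consumption; total
  grams purchased are fixed.
* ORs apply uniformly across the population (no age/sex/SES
  heterogeneity) and RRs have no age attenuation beyond configuration.
* The restricted scenario's merge-at-baseline-composition assumption
  can understate non-claim quality.
* All headline mortality numbers inherit the illustrative RR catalogue
  and the synthetic calibration; they demonstrate mechanism and
  machinery, not UK point predictions.
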