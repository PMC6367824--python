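"""Score foods against the nutrient profile models.

Shows the points-based score for one composition, then the per-group
prevalence of claim-carrying foods that would keep their claims under
each profile model.
"""

import hrcimpact as h
from hrcimpact.nutrients import NutrientVector
from hrcimpact.profiling import KJ_PER_KCAL

food = NutrientVector(energy_kcal=2000 / KJ_PER_KCAL, satfat_g=5,
                      sugars_g=20, sodium_mg=400, fibre_g=2, protein_g=5)
res = h.fsanz_score(food, category=2, fvnl_percent=0)
print(f"category-2 food: baseline {res.baseline_points} - modifying "
      f"{res.modifying_points} = score {res.final_score}; "
      f"{'passes' if res.passes else 'fails'} (threshold < 4)")

products = h.gen_product_survey(h.default_product_params(), 6000, seed=2)
q_base = h.estimate_prevalence(products)
for model in ("fsanz", "eu"):
    q_pass = h.pass_prevalence(products, model)
    print(f"\nclaim-and-pass prevalence under the {model} model:")
    for g in sorted(q_pass, key=lambda g: g.value):
        print(f"  {g.value:10s} {q_pass[g]:.3f}  "
              f"(baseline claim prevalence {q_base[g].q.point:.3f})")
print("\nthe pass prevalence can never exceed the baseline prevalence: "
      "only existing claim carriers can keep a claim.")
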