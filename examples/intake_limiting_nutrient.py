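"""How many grams of product meet each daily requirement, and what limits it.

For each product the daily requirement of every nutrient is divided by the
product's dry-basis density; the nutrient demanding the most grams is
limiting.  Two lysine requirements circulate in the source material; both
are shown because they change which nutrient limits product A.
"""

from rutfopt import fixtures, intake_needed

for variant in ("table", "figure"):
    req = fixtures.pregnancy_requirements(lysine=variant)
    print(f"lysine requirement {req.amino_acids_g_day['lys']} g/day ({variant}):")
    for mp in fixtures.measured_products():
        rep = intake_needed(req, mp.actual, product=mp.formulation_name)
        top = rep.ranked()[0]
        print(f"  product {rep.product}: limiting {rep.limiting_nutrient:6s}"
              f" needing {top[1]:6.1f} g dry/day"
              f" (energy requires {rep.per_nutrient_grams['energy']:.1f} g)")
    print()
print("With 3.62 g/day lysine limits every product; with 3.26 g/day the energy")
print("requirement overtakes lysine in product A. Macronutrient requirements")
print("need far less product, so meeting the limiting nutrient meets them all.")
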