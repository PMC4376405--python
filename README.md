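# rutfopt

Least-cost formulation and evaluation of ready-to-use therapeutic foods
(RUTFs) from local plant ingredients.

RUTFs are energy- and macronutrient-dense foods used to treat malnutrition
without clinical preparation. Formulating one from locally available
commodities is a classic *least-cost blending* problem: choose ingredient
percentages that minimize ingredient cost while meeting nutrient-density
floors and palatability ceilings. `rutfopt` implements that optimization and
every calculation around it for a Mali case study — six products blended
from peanuts, cowpeas, millet, sugar and rice or barley koji, targeted at
the daily requirements of pregnant women in their third trimester — with
the study's price, recipe, requirement and laboratory tables packaged as
fixtures.

## The model

Decision variables are ingredient mass percentages $x_i \in [0, 100]$:

$$\min_x \sum_i \frac{x_i}{100}\, p_i \quad \text{(USD per kg of blend)}$$

subject to

$$\sum_i x_i = 100, \qquad
m_n \le \sum_i \frac{x_i}{100}\, a_{ni} \le M_n \ \ \forall n, \qquad
l_i \le x_i \le u_i \ \ \forall i,$$

where $p_i$ is ingredient $i$'s price (USD/kg), $a_{ni}$ its content of
nutrient $n$ per 100 g, and $(m_n, M_n)$ the nutrient-density bounds — in
the study: fat ≤ 20 g/100 g, energy ≥ 452 kcal/100 g, sugar ≤ 14%, a koji
grain pinned at a fixed level (rice 7/14/21% or barley 5/10/15%), and
protein/amino-acid floors scaled from daily requirements. Fixed levels are
min = max box constraints, so discrete koji choices are a family of LPs,
not an integer program. The LP is solved with HiGHS via
`scipy.optimize.linprog`; solutions are re-verified against the constraint
spec independently of the solver.

Around the LP the package provides: linear blending of ingredient profiles
into predicted product profiles; Atwater energy ($4p + 9f + 4c$ kcal per
100 g); carbohydrate by difference ($100 - p - f - \text{ash} -
\text{fiber} - \text{moisture}$); predicted-vs-measured comparison tables;
grams-of-product-per-day intake analysis with limiting-nutrient
identification; multi-year ingredient-cost trends; and a synthetic-data
module that plants LP instances with *provably unique known optima* plus a
brute-force simplex-grid oracle to validate the solver.

## Worked example

```python
from rutfopt import build_cost_trend, fixtures

trend = build_cost_trend(fixtures.study_formulations(),
                         fixtures.mali_price_table(), range(2004, 2010))
print(round(trend.costs[("A", 2004)], 2))   # 0.33
print(round(trend.yearly_mean[2009], 2))    # 0.5
print(round(trend.rounded_mean_change(), 2))# 0.17
```

Producing 1 kg of recipe A cost $0.33 in ingredients at 2004 Mali prices;
by 2009 the six-recipe mean had risen to $0.50/kg — a $0.17/kg increase
driven by commodity prices, still far below the ~$3.40/kg ingredient share
of imported commercial RUTF.

Solving the least-cost LP directly
(`python examples/least_cost_formulation.py`):

```
status: optimal
ingredient cost: $0.1721 per kg of blend
optimal blend (percent by mass):
  corn        48.33
  peanuts     35.39
  cowpeas      9.28
  rice         7.00
binding constraints: energy:min, lys:min, barley:max, rice:max
```

The energy floor and the lysine floor are binding: they, not cost alone,
shape the recipe. Each script in `examples/` demonstrates one capability
(formulation, predicted-vs-actual comparison, intake and limiting nutrient,
cost trends, planted-optimum recovery) and prints what its numbers mean.

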