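# Methods

## Scope and data flow

`rutfopt` models the formulation stage of therapeutic-food development:
ingredient nutrient profiles and prices go in; a least-cost blend, its
predicted nutrient profile, the intake needed to satisfy daily
requirements, and multi-year cost trends come out. Laboratory work
(processing, assays, replicate statistics) is outside scope; measured
product values enter only as packaged tables for the comparison and intake
stages.

All composition values are per 100 g of food; formulations are mass percent
summing to 100; prices are USD/kg; requirements are per person per day.
Profiles carry an explicit basis (`dry` with zero moisture, or `as_is`);
operations that combine profiles refuse mixed bases rather than guessing a
conversion. Absences are preserved as absences: a missing amino acid or a
missing price cell raises when needed and is never imputed, interpolated or
treated as zero.

## The least-cost LP

Variables are ingredient percentages; the objective is ingredient cost of
1 kg of blend; constraints are one mass-balance equality, nutrient-density
rows built from linear blending coefficients, and per-ingredient box
bounds (min = max pins a fixed inclusion such as a koji grain). Solved with
HiGHS through `scipy.optimize.linprog`, which is deterministic for fixed
input; ties between equally cheap optima resolve to the solver's
deterministic vertex choice. Feasibility of reported optima is re-checked
independently of the solver at tolerance 1e-6 (`constraint_violations`),
and the same function audits fixed candidate recipes against any
constraint spec.

Daily requirements are converted to density floors by energy scaling:
`min_n = req_n × E_ref / req_energy`, with `E_ref` = 452 kcal/100 g, the
study's energy floor — a product dense enough to meet its energy floor
then meets every scaled floor when eaten in energy-sufficient quantity.
Because the source does not state which mapping its software used, a
scoring-pattern alternative (`mode="per_protein"`: amino-acid floors from
the AA:protein ratio times the protein floor) is provided; the default is
energy scaling.

Degenerate cases: a single-ingredient pool returns 100% of it when
feasible, otherwise infeasible status; infeasible and unbounded statuses
are reported, never raised.

### Known infeasibility of the published instance

The published recipes' predicted energies (440–441 kcal/100 g) sit *below*
the stated 452 kcal/100 g floor; the source does not reconcile this. With
the packaged reference profiles (whose as-entered energies blend to ~441,
matching the published predictions) the full restriction set is feasible
only at low koji levels (rice 7/14%, barley 5%); at rice 21% or barley
10/15% the energy floor plus the 20% fat cap cannot both hold. The package
therefore *audits* candidate recipes against the restriction set and
reports violations instead of asserting the published instance is
feasible; re-solving is not expected to recover the published percentages,
and solver validation rests on the planted-optimum suite instead.

## Blending and the two energy pathways

A product profile is the percentage-weighted mean of ingredient profiles.
Energy is blended from ingredient energy values *as entered*, not
recomputed from blended macros, because formulation software carries
ingredient energies as data. Atwater recomputation (4/9/4 kcal/g for
protein/fat/carbohydrate) is exposed separately: the published predicted
energies (~441) are consistent with blending as-entered energies but not
with Atwater on the predicted macros (~460), so both pathways are exposed
and labeled rather than silently reconciled. Carbohydrate by difference is
`100 − protein − fat − ash − fiber − moisture`.

Display rounding follows the source tables (energy to 3 significant
figures, macros to 1 decimal, amino acids to 2); stored values are never
rounded.

Comparison tables compute actual − predicted from the supplied values and
flag rows whose result disagrees with the published difference by more
than 0.005 (one printed-precision unit): such disagreement means the
source differenced unrounded laboratory values. The threshold is one
display unit, not the 0.05 a naive reading might suggest, because typical
disagreements (e.g. lysine: −0.18 from printed cells vs −0.17 published)
are exactly one hundredth.

## Intake and limiting nutrient

Dry grams needed per nutrient: `100 × requirement / density`. The limiting
nutrient maximizes grams; meeting it meets everything (grams are
inversely proportional to density, so the maximum dominates — asserted,
not assumed, in `limiting_nutrient_ranking`). Ties break alphabetically
and are flagged. Wet-basis grams (`dry / (1 − moisture/100)`) are computed
only when the caller supplies a moisture content, since product moisture
is not published; the published 2620–3002 g wet-intake range is therefore
a qualitative check only.

Two lysine requirements circulate in the source: 3.26 g/day in the
requirement table and 3.62 g/day in the intake-figure caption. The default
`RequirementSet` carries 3.26; `pregnancy_requirements(lysine="figure")`
selects 3.62. The distinction matters: with 3.62 lysine limits all six
products (the published finding), while with 3.26 the energy requirement
overtakes lysine in product A (572.3 g vs 552.5 g dry). The package
defaults to the table value and reproduces the published finding under the
figure value.

## Cost trends

Costs are ingredient-only per kg of blend mass, with no yield or moisture
correction — the published table reproduces without one. Yearly SD across
recipes is the sample (n−1) SD, reported absent for a single recipe. The
exact first-to-last change per recipe is exposed alongside
`rounded_mean_change`, the difference of the 2-decimal-rounded yearly
means, which is how the published $0.17/kg headline was computed (the
unrounded difference is $0.163/kg).

Recomputing all 36 recipe-year cells from the printed prices leaves 32
within ±0.005 USD/kg; four (D-2005, A-2006, A-2007, F-2007) miss by up to
0.0054 because the source's software used unrounded price series while the
printed table carries cents (an unrounded millet price near 0.195 in 2006,
printed 0.20, reconciles all six 2006 cells). The corresponding acceptance
test asserts the ±0.005 band for all 36 cells and fails on those four —
retained deliberately as an honest record of printed-precision limits.

## Packaged reference profiles

The source does not publish the ingredient nutrient profiles its software
used (it cites whole-commodity database entries while processing used
decorticated, roasted, milled and fermented forms). The packaged 12-
ingredient table is a clearly labeled *reference approximation*, dry
basis: the six recipe ingredients were reconstructed by bounded least
squares — fitting the recipe matrix to the published predicted product
values within plausible composition bounds, then scaling fat by 0.99932 so
every published recipe satisfies the 20% fat cap — and the other six are
hand-set, database-style approximations. Blends of these profiles
reproduce the published predicted columns within 0.1 g/100 g for macros,
1 kcal for energy and 0.05 g/100 g for amino acids (carbohydrate within
2.5, as the source's carbohydrate convention is unstated). Nothing
quantitative is claimed beyond those bands, and the acceptance quantities
avoid depending on exact fixture values.

Published-table quirks handled explicitly: recipe F's percentages sum to
100.1 (balance tolerance is ±0.1, one display unit); predicted proximate
rows sum to up to 101.33 (profile mass slack 1.5); product F's published
predicted Phe+Tyr (1.60) contradicts its own components (1.57), so that
one stored sum is dropped and computed from components.

## Synthetic instances and the oracle

`generate_pool` draws macros uniformly within ranges spanning common
cereal/legume/oilseed commodities (defaults: protein 2–30, fat 0.5–50,
ash 0.5–5, fiber 1–13 g/100 g), rescales if the sum exceeds 99, fills
carbohydrate to 100 and sets energy by Atwater; prices are uniform in
0.06–1.05 USD/kg (the span of the packaged price table) drifting ×1.09 per
year (the observed 2004–2009 trend). All randomness flows through NumPy's
seeded PCG64 generator, whose stream is platform-independent. The pool
emulates marginal ranges only — no amino-acid/protein correlation
structure, no price co-movement — so passing tests validate the
*arithmetic*, not distributional realism.

`plant_optimum` constructs instances whose unique optimum is known by
dual certificate: for a blend with k positive components it draws k−1
random nutrient rows, sets those nutrient minima exactly at the blend's
own values (binding), and prices each ingredient as the dual-weighted
nutrient value plus a constant, plus a strictly positive markup
(0.01 × `margin` USD/kg) on every ingredient the blend excludes.
Complementary slackness makes the blend optimal; the positive reduced cost
forces excluded ingredients to zero; the almost-surely independent random
rows pin the support uniquely. `margin ≤ 0` warns of a degenerate face.
Uniqueness is additionally certified against the oracle for instances
small enough to enumerate. (An earlier sketch placing minima *below* the
blended values was rejected: non-binding floors leave the blend
non-optimal.)

`enumerate_oracle` exhaustively scans the simplex grid (step must divide
100; at most 3 free ingredients, ~500k points at 0.1% — kept to 3 free
dimensions so a scan stays well under a second) and shares no code with
the LP path. Solver validation: solver-vs-oracle cost agreement within
0.001 USD/kg on 50 planted instances, ≥ 99/100 planted-blend recoveries
within 0.1 percentage points per ingredient across seeds 1–100, exact
cost scaling under price doubling (a power of two, so scaling is exact in
floating point), and weak duality against 1000 random feasible points.

## Problem sizes

The packaged analyses are tiny (12 ingredients, 6 recipes, 6 years). The
synthetic suites use 3-ingredient instances at 0.1% grid resolution (the
largest exhaustively enumerable size), 50 instances for oracle agreement
and 100 for recovery; the whole test suite and the acceptance script each
run in a few seconds on one CPU.
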