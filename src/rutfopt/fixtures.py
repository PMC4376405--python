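"""Packaged reference tables for the Mali RUTF study.

What is packaged
----------------
* ``mali_price_table`` — ingredient prices in Mali, 2004-2009 (USD/kg).
  Eleven priced ingredients; the barley series is from Algeria (no Malian
  barley prices exist) and sugar has a single newspaper price repeated
  across years.  Sesame has no price series at all.
* ``pregnancy_requirements`` — daily macronutrient and essential amino-acid
  requirements of a pregnant woman in her third trimester; amino acids follow
  the scoring pattern for 1- to 3-year-old children.  Two lysine values
  circulate in the source material (3.26 vs 3.62 g/day) and both are offered.
* ``study_formulations`` — the six selected recipes A-F (rice-koji products
  A-C at 7/14/21% rice, barley-koji products D-F at 5/10/15% barley).
* ``measured_products`` — software-predicted vs laboratory-measured dry-basis
  profiles of the six products, with the published actual-minus-predicted
  differences.
* ``reference_ingredients`` — dry-basis nutrient profiles of the twelve
  candidate ingredients.  These are a *reference approximation*: the source
  material does not publish the ingredient profiles it used, so the six
  recipe ingredients were reconstructed by bounded least squares against the
  published predicted product values, and the remaining six are hand-set
  USDA-style approximations.  Treat them as editable scaffolding, not
  authoritative composition data.
"""

from __future__ import annotations

from importlib import resources

from .model import (
    Formulation,
    Ingredient,
    MeasuredProduct,
    NutrientProfile,
    PriceTable,
    RequirementSet,
    load_formulations,
    load_ingredient_set,
    load_price_table,
    load_requirement_set,
)

#: Lysine requirement printed in the study's intake figure caption (g/day);
#: the requirement table itself prints 3.26.  Only 3.62 reproduces the
#: reported finding that lysine limits intake in all six products.
LYSINE_FIGURE_G_DAY = 3.62

PRODUCT_NAMES = ("A", "B", "C", "D", "E", "F")


def _data_path(name: str):
    return resources.files("rutfopt.data") / name


def mali_price_table() -> PriceTable:
    """Ingredient x year price matrix for Mali, 2004-2009 (USD/kg)."""
    with resources.as_file(_data_path("mali_prices_2004_2009.csv")) as p:
        return load_price_table(p)


def reference_ingredients() -> list[Ingredient]:
    """Dry-basis reference-approximation profiles of the 12 candidate ingredients."""
    with resources.as_file(_data_path("ingredient_profiles_reference_approx.csv")) as p:
        return load_ingredient_set(p)


def study_formulations() -> list[Formulation]:
    """The six selected RUTF recipes (A-F), percentages summing to 100."""
    with resources.as_file(_data_path("rutf_formulations.csv")) as p:
        return load_formulations(p)


def pregnancy_requirements(lysine: str = "table") -> RequirementSet:
    """Daily requirements for the third trimester of pregnancy.

    Parameters
    ----------
    lysine:
        ``"table"`` uses the requirement table's 3.26 g/day;
        ``"figure"`` uses the intake figure caption's 3.62 g/day
        (:data:`LYSINE_FIGURE_G_DAY`).
    """
    with resources.as_file(_data_path("requirements_third_trimester.json")) as p:
        req = load_requirement_set(p)
    if lysine == "table":
        return req
    if lysine == "figure":
        return req.replace_amino_acid("lys", LYSINE_FIGURE_G_DAY)
    raise ValueError(f"lysine must be 'table' or 'figure', got {lysine!r}")


def measured_products() -> list[MeasuredProduct]:
    """Predicted and measured dry-basis profiles of products A-F.

    Both profiles carry the published macro values plus the amino-acid rows;
    the published actual-minus-predicted differences are attached as
    ``reported_differences`` so the comparison stage can flag rows where the
    published difference was taken on unrounded values.  One published cell
    (product F, predicted Phe+Tyr) contradicts its own components beyond
    rounding slack; its stored sum is omitted and computed from components.
    """
    import csv

    rows = []
    with resources.as_file(_data_path("measured_products.csv")) as p:
        with open(p, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = []
    for prod in PRODUCT_NAMES:
        pred_mac: dict[str, float] = {}
        act_mac: dict[str, float] = {}
        pred_aa: dict[str, float] = {}
        act_aa: dict[str, float] = {}
        reported: dict[str, float] = {}
        for row in rows:
            if row["product"] != prod:
                continue
            nut = row["nutrient"]
            if row["reported_difference"]:
                reported[nut] = float(row["reported_difference"])
            pred, act = row["predicted"], row["actual"]
            if nut in ("protein", "fat", "ash", "fiber", "carbohydrate", "energy"):
                pred_mac[nut] = float(pred)
                act_mac[nut] = float(act)
            else:
                if pred:
                    pred_aa[nut] = float(pred)
                if act:
                    act_aa[nut] = float(act)

        def _profile(mac: dict[str, float], aa: dict[str, float]) -> NutrientProfile:
            return NutrientProfile(
                protein_pct=mac["protein"], fat_pct=mac["fat"], ash_pct=mac["ash"],
                fiber_pct=mac["fiber"], carbohydrate_pct=mac["carbohydrate"],
                energy_kcal=mac["energy"], moisture_pct=0.0, basis="dry",
                amino_acids=aa)

        out.append(MeasuredProduct(formulation_name=prod,
                                   predicted=_profile(pred_mac, pred_aa),
                                   actual=_profile(act_mac, act_aa),
                                   reported_differences=reported))
    return out


def plumpynut_reference() -> NutrientProfile:
    """Published composition of the commercial peanut-paste RUTF (per 100 g).

    Only energy (545 kcal), protein (13.6 g) and fat (35.7 g) are published;
    carbohydrate is back-computed from the Atwater identity and ash/fiber are
    unknown (set to 0), so use this profile for energy/protein/fat fold
    comparisons only.
    """
    carb = (545 - 4 * 13.6 - 9 * 35.7) / 4
    return NutrientProfile(protein_pct=13.6, fat_pct=35.7, ash_pct=0.0, fiber_pct=0.0,
                           carbohydrate_pct=carb, energy_kcal=545.0, basis="as_is",
                           moisture_pct=0.0)
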