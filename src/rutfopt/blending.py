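"""Linear blending of ingredient profiles and predicted-vs-actual comparison.

A product's predicted profile is the percentage-weighted mean of its
ingredient profiles: nutrient_product = sum_i (pct_i / 100) * nutrient_i.
Energy is blended from the ingredient energy values as entered, *not*
recomputed by Atwater factors from the blended macros — formulation software
carries ingredient energies as data, and the two pathways disagree whenever
the ingredient energies are not themselves Atwater-consistent.  Both
pathways are exposed (:func:`blend_profile` vs :func:`atwater_energy`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    BasisError,
    DataValidationError,
    InfeasibleCompositionError,
    KeyMismatchError,
)
from .model import (
    AA_SUMS,
    AMINO_ACIDS,
    Formulation,
    Ingredient,
    IngredientSet,
    MeasuredProduct,
    NutrientProfile,
    as_ingredient_set,
    validate_formulation,
)

#: Difference (in display units) beyond which a computed actual-minus-predicted
#: value is flagged as disagreeing with the published difference: published
#: differences were evidently taken on unrounded values, so disagreement at
#: the printed precision is informative, not an error.
FLAG_TOLERANCE = 0.005


class PartialProfileWarning(UserWarning):
    """Some amino acids were absent from at least one component and omitted."""


def blend_profile(f: Formulation,
                  ingredients: IngredientSet | Iterable[Ingredient]) -> NutrientProfile:
    """Blend ingredient profiles into the predicted product profile.

    Every macro (and energy) is the percentage-weighted mean of the component
    values.  Amino acids are blended only for keys present in *every*
    component; omitted keys trigger a :class:`PartialProfileWarning` listing
    them.  All components must share one basis.
    """
    ingset = as_ingredient_set(ingredients)
    validate_formulation(f, ingset)
    profiles = {name: ingset[name].profile for name in f.components}
    bases = {p.basis for p in profiles.values()}
    if len(bases) > 1:
        raise BasisError(f"mixed bases among components: {sorted(bases)}")
    basis = bases.pop()

    def wmean(values: dict[str, float]) -> float:
        return sum(f.components[n] / 100.0 * values[n] for n in f.components)

    aa_keys = set(AMINO_ACIDS) | set(AA_SUMS)
    common = [k for k in sorted(aa_keys)
              if all(p.has_nutrient(k) for p in profiles.values())]
    omitted = [k for k in sorted(aa_keys - set(common))
               if any(p.has_nutrient(k) for p in profiles.values())]
    if omitted:
        warnings.warn(
            f"amino acids omitted from blend (absent in some component): {omitted}",
            PartialProfileWarning, stacklevel=2)
    amino = {k: wmean({n: p.nutrient(k) for n, p in profiles.items()})
             for k in common if k in AMINO_ACIDS}
    return NutrientProfile(
        protein_pct=wmean({n: p.protein_pct for n, p in profiles.items()}),
        fat_pct=wmean({n: p.fat_pct for n, p in profiles.items()}),
        ash_pct=wmean({n: p.ash_pct for n, p in profiles.items()}),
        fiber_pct=wmean({n: p.fiber_pct for n, p in profiles.items()}),
        carbohydrate_pct=wmean({n: p.carbohydrate_pct for n, p in profiles.items()}),
        energy_kcal=wmean({n: p.energy_kcal for n, p in profiles.items()}),
        moisture_pct=wmean({n: p.moisture_pct for n, p in profiles.items()}),
        basis=basis,
        amino_acids=amino,
    )


def atwater_energy(protein: float, fat: float, carbohydrate: float) -> float:
    """Food energy (kcal) from macros (g) at 4/9/4 kcal per g of protein/fat/carbohydrate."""
    for name, v in (("protein", protein), ("fat", fat), ("carbohydrate", carbohydrate)):
        if not math.isfinite(v) or v < 0:
            raise DataValidationError(f"{name} must be finite and >= 0, got {v}")
    return 4.0 * protein + 9.0 * fat + 4.0 * carbohydrate


def carbohydrate_by_difference(protein: float, fat: float, ash: float, fiber: float,
                               moisture: float = 0.0) -> float:
    """Total carbohydrate as 100 minus the other proximate components (g/100 g).

    With ``moisture=0`` this is the dry-basis convention.
    """
    for name, v in (("protein", protein), ("fat", fat), ("ash", ash),
                    ("fiber", fiber), ("moisture", moisture)):
        if not math.isfinite(v) or v < 0:
            raise DataValidationError(f"{name} must be finite and >= 0, got {v}")
    total = protein + fat + ash + fiber + moisture
    if total > 100.0:
        raise InfeasibleCompositionError(
            f"proximate components sum to {total:.2f} > 100")
    return 100.0 - total


@dataclass(frozen=True)
class ComparisonRow:
    nutrient: str
    product: str
    predicted: float
    actual: float
    abs_difference: float  # actual - predicted (sign preserved)
    flag: bool             # disagrees with the published difference


@dataclass(frozen=True)
class ComparisonTable:
    """Long-format predicted/actual/difference table for a set of products."""

    rows: tuple[ComparisonRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows],
                            columns=["nutrient", "product", "predicted", "actual",
                                     "abs_difference", "flag"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


_COMPARED_MACROS = ("protein", "fat", "ash", "fiber", "carbohydrate", "energy")


def compare_predicted_actual(products: Sequence[MeasuredProduct]) -> ComparisonTable:
    """Build the predicted-vs-actual comparison for a list of measured products.

    The difference column is actual minus predicted, computed from the
    supplied (possibly rounded) values.  When a product carries published
    differences, rows whose computed difference disagrees with the published
    one by more than :data:`FLAG_TOLERANCE` are flagged.  A nutrient present
    in only one of the two profiles raises :class:`KeyMismatchError`.
    """
    rows: list[ComparisonRow] = []
    aa_keys = tuple(AMINO_ACIDS) + tuple(AA_SUMS)
    for mp in products:
        nutrients = list(_COMPARED_MACROS)
        for k in aa_keys:
            in_pred = mp.predicted.has_nutrient(k)
            in_act = mp.actual.has_nutrient(k)
            if in_pred != in_act:
                raise KeyMismatchError(
                    f"product {mp.formulation_name!r}: nutrient {k!r} present in "
                    f"{'predicted' if in_pred else 'actual'} profile only")
            if in_pred:
                nutrients.append(k)
        for nut in nutrients:
            pred = mp.predicted.nutrient(nut)
            act = mp.actual.nutrient(nut)
            diff = act - pred
            flag = False
            if mp.reported_differences and nut in mp.reported_differences:
                flag = abs(diff - mp.reported_differences[nut]) > FLAG_TOLERANCE
            rows.append(ComparisonRow(nut, mp.formulation_name, pred, act, diff, flag))
    return ComparisonTable(tuple(rows))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to significant figures (display only; stored values stay unrounded)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def format_nutrient(nutrient: str, value: float) -> str:
    """Display formatting: energy to 3 significant figures, percentages to one
    decimal, amino acids to two decimals."""
    if nutrient == "energy":
        v = round_sig(value, 3)
        return f"{v:.0f}" if v >= 100 else f"{v:g}"
    if nutrient in _COMPARED_MACROS:
        return f"{value:.1f}"
    return f"{value:.2f}"
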