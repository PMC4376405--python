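"""Intake analysis: grams of product needed per nutrient, limiting nutrient,
and fold comparison against reference products.

For each nutrient n with daily requirement req_n and dry-basis density d_n
(per 100 g), the dry mass needed is ``100 * req_n / d_n``.  The *limiting
nutrient* is the one demanding the largest mass: eating enough product to
satisfy it automatically satisfies every other modeled requirement (grams
needed is inversely proportional to density, so the maximum dominates).
Wet-basis masses are reported only when a moisture content is supplied —
they are never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataValidationError, UnmeetableRequirementError
from .model import NutrientProfile, RequirementSet


@dataclass(frozen=True)
class IntakeReport:
    """Grams of one product needed to satisfy each daily requirement."""

    product: str
    per_nutrient_grams: Mapping[str, float]          # dry basis
    per_nutrient_grams_wet: Mapping[str, float] | None
    limiting_nutrient: str
    tied_nutrients: tuple[str, ...] = ()             # non-empty flags a tie

    def ranked(self) -> list[tuple[str, float]]:
        """Nutrients sorted by grams needed, descending (alphabetical tie-break)."""
        return sorted(self.per_nutrient_grams.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {"product": self.product,
                "per_nutrient_grams": dict(self.per_nutrient_grams),
                "per_nutrient_grams_wet": (None if self.per_nutrient_grams_wet is None
                                           else dict(self.per_nutrient_grams_wet)),
                "limiting_nutrient": self.limiting_nutrient,
                "tied_nutrients": list(self.tied_nutrients)}


def intake_needed(req: RequirementSet, actual: NutrientProfile,
                  moisture_pct: float | None = None,
                  product: str = "product") -> IntakeReport:
    """Compute the intake report for one product.

    ``actual`` must be a dry-basis profile covering every requirement
    nutrient; a zero density raises :class:`UnmeetableRequirementError`
    naming the nutrient.  ``moisture_pct`` (g water per 100 g wet product)
    enables the wet-basis column: wet = dry / (1 - moisture/100).
    """
    if actual.basis != "dry":
        raise DataValidationError("intake analysis requires a dry-basis profile")
    grams: dict[str, float] = {}
    for nut, amount in req.items():
        try:
            density = actual.nutrient(nut)
        except KeyError:
            raise UnmeetableRequirementError(
                f"product {product!r}: nutrient {nut!r} absent from profile") from None
        if density <= 0:
            raise UnmeetableRequirementError(
                f"product {product!r}: zero density for required nutrient {nut!r}")
        grams[nut] = 100.0 * amount / density
    top = max(grams.values())
    at_top = sorted(n for n, g in grams.items() if g == top)
    limiting = at_top[0]
    ties = tuple(at_top) if len(at_top) > 1 else ()
    wet = None
    if moisture_pct is not None:
        if not 0 <= moisture_pct < 100:
            raise DataValidationError(f"moisture_pct must be in [0, 100), got {moisture_pct}")
        wet = {n: g / (1.0 - moisture_pct / 100.0) for n, g in grams.items()}
    return IntakeReport(product=product, per_nutrient_grams=grams,
                        per_nutrient_grams_wet=wet, limiting_nutrient=limiting,
                        tied_nutrients=ties)


def limiting_nutrient_ranking(reports: Sequence[IntakeReport]) -> pd.DataFrame:
    """Rank nutrients by required grams for each product.

    Returns a long DataFrame (product, rank, nutrient, grams_dry, limiting)
    and asserts the dominance property: the top-ranked nutrient's intake
    covers every other requirement.
    """
    if not reports:
        raise DataValidationError("need at least one intake report")
    rows = []
    for rep in reports:
        ranked = rep.ranked()
        top_grams = ranked[0][1]
        assert all(top_grams >= g for _, g in ranked), "top-ranked intake must dominate"
        for rank, (nut, g) in enumerate(ranked, start=1):
            rows.append({"product": rep.product, "rank": rank, "nutrient": nut,
                         "grams_dry": g, "limiting": nut == rep.limiting_nutrient})
    return pd.DataFrame(rows, columns=["product", "rank", "nutrient", "grams_dry",
                                       "limiting"])


def fold_comparison(actual: NutrientProfile, reference: NutrientProfile,
                    nutrients: Sequence[str] = ("energy", "protein", "fat"),
                    ) -> dict[str, tuple[float, str]]:
    """Fold difference per nutrient against a reference product.

    Returns ``{nutrient: (fold, direction)}`` with fold = max/min >= 1 and
    direction ``"more"``/``"less"``/``"equal"`` describing the actual product
    relative to the reference.
    """
    out: dict[str, tuple[float, str]] = {}
    for nut in nutrients:
        a = actual.nutrient(nut)
        r = reference.nutrient(nut)
        if r <= 0:
            raise DataValidationError(f"reference density for {nut!r} must be > 0")
        if a <= 0:
            raise DataValidationError(f"actual density for {nut!r} must be > 0")
        if a == r:
            out[nut] = (1.0, "equal")
        elif a > r:
            out[nut] = (a / r, "more")
        else:
            out[nut] = (r / a, "less")
    return out
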