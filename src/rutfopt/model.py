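"""Domain types and file I/O for ingredients, prices, formulations and requirements.

Conventions
-----------
* All composition values are per 100 g of food (g/100 g; energy kcal/100 g).
* Formulation components are mass percent (0-100), never fractions.
* A profile is either ``"dry"`` (moisture 0) or ``"as_is"`` (moisture included).
* Amino acids are stored individually under the keys in :data:`AMINO_ACIDS`;
  the scoring sums ``met_cys`` and ``phe_tyr`` are computed on demand, but a
  stored sum (as printed in some source tables) takes precedence.
* Missing values are absences, never zeros: an absent amino acid or price
  cell raises when used rather than silently contributing 0.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    DataValidationError,
    EmptyTableError,
    FormulationImbalanceError,
    MissingPriceError,
    SchemaError,
    UnknownIngredientError,
)

#: Canonical individual amino-acid keys (g/100 g).
AMINO_ACIDS = ("lys", "leu", "val", "his", "trp", "thr", "ile", "met", "cys", "phe", "tyr")

#: Scoring-pattern sums -> their components.
AA_SUMS: dict[str, tuple[str, str]] = {"met_cys": ("met", "cys"), "phe_tyr": ("phe", "tyr")}

#: Macro fields addressable through :meth:`NutrientProfile.nutrient`.
MACRO_KEYS = ("protein", "fat", "ash", "fiber", "carbohydrate", "energy", "moisture")

_SUM_SLACK = 0.015  # rounding slack for stored met_cys / phe_tyr sums
# Proximate components may exceed 100 by this much.  Wider than pure rounding
# because published predicted rows can carry a carbohydrate value that was not
# taken by difference (observed excess up to 1.33 in the packaged tables).
_MASS_SLACK = 1.5
# Formulation percentages must sum to 100 +/- this.  One published recipe
# sums to 100.1 (components printed to 1 decimal), so the slack is one
# display unit rather than half of one.
_PCT_SLACK = 0.1


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g nutrient vector of one ingredient or one product."""

    protein_pct: float
    fat_pct: float
    ash_pct: float
    fiber_pct: float
    carbohydrate_pct: float
    energy_kcal: float
    moisture_pct: float = 0.0
    basis: str = "dry"
    amino_acids: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.basis not in ("dry", "as_is"):
            raise DataValidationError(f"basis must be 'dry' or 'as_is', got {self.basis!r}")
        for name in ("protein_pct", "fat_pct", "ash_pct", "fiber_pct",
                     "carbohydrate_pct", "energy_kcal", "moisture_pct"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DataValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.basis == "dry" and self.moisture_pct != 0:
            raise DataValidationError("dry-basis profile must have moisture_pct == 0")
        total = (self.protein_pct + self.fat_pct + self.ash_pct + self.fiber_pct
                 + self.carbohydrate_pct + self.moisture_pct)
        if total > 100 + _MASS_SLACK:
            raise DataValidationError(
                f"proximate components sum to {total:.2f} > {100 + _MASS_SLACK}")
        aa = dict(self.amino_acids)
        for k, v in aa.items():
            if k not in AMINO_ACIDS and k not in AA_SUMS:
                raise SchemaError(f"unknown amino-acid key {k!r}")
            if not math.isfinite(v) or v < 0:
                raise DataValidationError(f"amino acid {k} must be finite and >= 0, got {v}")
        for total_key, (a, b) in AA_SUMS.items():
            if total_key in aa and a in aa and b in aa:
                if abs(aa[total_key] - (aa[a] + aa[b])) > _SUM_SLACK:
                    raise DataValidationError(
                        f"stored {total_key}={aa[total_key]} inconsistent with "
                        f"{a}+{b}={aa[a] + aa[b]:.3f} (slack {_SUM_SLACK})")
        object.__setattr__(self, "amino_acids", aa)

    def nutrient(self, name: str) -> float:
        """Return a nutrient by canonical name.

        Macro names are ``protein``, ``fat``, ``ash``, ``fiber``,
        ``carbohydrate``, ``energy``, ``moisture``; amino acids by their key;
        ``met_cys``/``phe_tyr`` fall back to the component sum when no stored
        value exists.  Raises :class:`KeyError` for an absent nutrient.
        """
        if name in ("protein", "fat", "ash", "fiber", "carbohydrate", "moisture"):
            return getattr(self, f"{name}_pct")
        if name == "energy":
            return self.energy_kcal
        if name in self.amino_acids:
            return self.amino_acids[name]
        if name in AA_SUMS:
            a, b = AA_SUMS[name]
            if a in self.amino_acids and b in self.amino_acids:
                return self.amino_acids[a] + self.amino_acids[b]
        raise KeyError(name)

    def has_nutrient(self, name: str) -> bool:
        try:
            self.nutrient(name)
            return True
        except KeyError:
            return False

    @property
    def met_cys(self) -> float:
        return self.nutrient("met_cys")

    @property
    def phe_tyr(self) -> float:
        return self.nutrient("phe_tyr")

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "protein_pct": self.protein_pct,
            "fat_pct": self.fat_pct,
            "ash_pct": self.ash_pct,
            "fiber_pct": self.fiber_pct,
            "carbohydrate_pct": self.carbohydrate_pct,
            "energy_kcal": self.energy_kcal,
            "moisture_pct": self.moisture_pct,
            "amino_acids": dict(self.amino_acids),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NutrientProfile":
        return cls(
            protein_pct=float(d["protein_pct"]),
            fat_pct=float(d["fat_pct"]),
            ash_pct=float(d["ash_pct"]),
            fiber_pct=float(d["fiber_pct"]),
            carbohydrate_pct=float(d["carbohydrate_pct"]),
            energy_kcal=float(d["energy_kcal"]),
            moisture_pct=float(d.get("moisture_pct", 0.0)),
            basis=str(d.get("basis", "dry")),
            amino_acids={k: float(v) for k, v in dict(d.get("amino_acids", {})).items()},
        )


@dataclass(frozen=True)
class Ingredient:
    """A named ingredient with its nutrient profile and free-text notes."""

    name: str
    profile: NutrientProfile
    notes: str = ""

    def __post_init__(self):
        if not self.name:
            raise DataValidationError("ingredient name must be non-empty")


IngredientSet = dict[str, Ingredient]


def as_ingredient_set(ingredients: Iterable[Ingredient] | IngredientSet) -> IngredientSet:
    """Normalize a list of ingredients to a name-keyed dict, enforcing unique names."""
    if isinstance(ingredients, dict):
        return ingredients
    out: IngredientSet = {}
    for ing in ingredients:
        if ing.name in out:
            raise DataValidationError(f"duplicate ingredient name {ing.name!r}")
        out[ing.name] = ing
    return out


@dataclass(frozen=True)
class Formulation:
    """A named recipe: ingredient -> mass percent, summing to 100."""

    name: str
    components: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "components", dict(self.components))

    @property
    def total(self) -> float:
        return sum(self.components.values())

    def to_dict(self) -> dict:
        return {"name": self.name, "components": dict(self.components)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Formulation":
        return cls(name=str(d["name"]),
                   components={k: float(v) for k, v in dict(d["components"]).items()})


def validate_formulation(f: Formulation,
                         ingredients: IngredientSet | Iterable[Ingredient] | None = None,
                         ) -> Formulation:
    """Return ``f`` unchanged iff it is a valid formulation.

    Checks that every percentage is >= 0, that they sum to 100 within 0.05,
    and (when an ingredient set is supplied) that every component name is
    known.  Raises :class:`FormulationImbalanceError` reporting the offending
    sum, or :class:`UnknownIngredientError`.
    """
    for ing, pct in f.components.items():
        if not math.isfinite(pct) or pct < 0:
            raise DataValidationError(
                f"formulation {f.name!r}: component {ing!r} has percentage {pct}")
    if abs(f.total - 100.0) > _PCT_SLACK:
        raise FormulationImbalanceError(f.name, f.total)
    if ingredients is not None:
        known = as_ingredient_set(ingredients)
        unknown = sorted(set(f.components) - set(known))
        if unknown:
            raise UnknownIngredientError(
                f"formulation {f.name!r} references unknown ingredient(s): {unknown}")
    return f


class PriceTable:
    """Ingredient x year matrix of USD/kg prices; absent cells stay absent."""

    def __init__(self, entries: Mapping[tuple[str, int], float]):
        self.entries: dict[tuple[str, int], float] = {}
        for (ing, year), price in entries.items():
            p = float(price)
            if not math.isfinite(p) or p <= 0:
                raise DataValidationError(f"price for ({ing}, {year}) must be > 0, got {price}")
            self.entries[(str(ing), int(year))] = p
        if not self.entries:
            raise EmptyTableError("price table has no entries")

    @property
    def ingredients(self) -> list[str]:
        return sorted({ing for ing, _ in self.entries})

    @property
    def years(self) -> list[int]:
        return sorted({year for _, year in self.entries})

    def price(self, ingredient: str, year: int) -> float:
        try:
            return self.entries[(ingredient, int(year))]
        except KeyError:
            raise MissingPriceError(f"no price for ({ingredient}, {year})") from None

    def has(self, ingredient: str, year: int) -> bool:
        return (ingredient, int(year)) in self.entries

    def for_year(self, year: int, ingredients: Sequence[str] | None = None) -> dict[str, float]:
        """Prices of the given (default: all priced) ingredients in one year."""
        names = ingredients if ingredients is not None else [
            ing for ing in self.ingredients if self.has(ing, year)]
        return {ing: self.price(ing, year) for ing in names}

    def __eq__(self, other):
        return isinstance(other, PriceTable) and self.entries == other.entries


@dataclass(frozen=True)
class RequirementSet:
    """Daily nutrient requirements (per person per day)."""

    energy_kcal_day: float
    protein_g_day: float
    carbohydrate_g_day: float
    fat_g_day: float
    amino_acids_g_day: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("energy_kcal_day", "protein_g_day", "carbohydrate_g_day", "fat_g_day"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise DataValidationError(f"{name} must be > 0, got {v}")
        aa = dict(self.amino_acids_g_day)
        for k, v in aa.items():
            if k not in AMINO_ACIDS and k not in AA_SUMS:
                raise SchemaError(f"unknown amino-acid key {k!r}")
            if not math.isfinite(v) or v <= 0:
                raise DataValidationError(f"requirement for {k} must be > 0, got {v}")
        object.__setattr__(self, "amino_acids_g_day", aa)

    def items(self) -> list[tuple[str, float]]:
        """(nutrient, daily amount) pairs; energy in kcal, the rest in grams."""
        out = [("energy", self.energy_kcal_day),
               ("protein", self.protein_g_day),
               ("carbohydrate", self.carbohydrate_g_day),
               ("fat", self.fat_g_day)]
        out.extend(sorted(self.amino_acids_g_day.items()))
        return out

    def replace_amino_acid(self, key: str, grams_per_day: float) -> "RequirementSet":
        aa = dict(self.amino_acids_g_day)
        aa[key] = grams_per_day
        return RequirementSet(self.energy_kcal_day, self.protein_g_day,
                              self.carbohydrate_g_day, self.fat_g_day, aa)

    def to_dict(self) -> dict:
        return {
            "energy_kcal_day": self.energy_kcal_day,
            "protein_g_day": self.protein_g_day,
            "carbohydrate_g_day": self.carbohydrate_g_day,
            "fat_g_day": self.fat_g_day,
            "amino_acids_g_day": dict(self.amino_acids_g_day),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RequirementSet":
        return cls(
            energy_kcal_day=float(d["energy_kcal_day"]),
            protein_g_day=float(d["protein_g_day"]),
            carbohydrate_g_day=float(d["carbohydrate_g_day"]),
            fat_g_day=float(d["fat_g_day"]),
            amino_acids_g_day={k: float(v)
                               for k, v in dict(d.get("amino_acids_g_day", {})).items()},
        )


@dataclass(frozen=True)
class MeasuredProduct:
    """Predicted vs laboratory-measured profile of one product.

    ``reported_differences`` optionally carries the source table's printed
    actual-minus-predicted differences, used to flag rows where the printed
    difference was evidently taken on unrounded values.
    """

    formulation_name: str
    predicted: NutrientProfile
    actual: NutrientProfile
    reported_differences: Mapping[str, float] | None = None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_PROFILE_REQUIRED = ("name", "protein_pct", "fat_pct", "ash_pct", "fiber_pct",
                     "carbohydrate_pct", "energy_kcal")
_PROFILE_COLUMNS = _PROFILE_REQUIRED + ("moisture_pct", "basis") + AMINO_ACIDS + ("notes",)


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise DataValidationError(f"unparsable number {text!r} at {where}") from None


def load_ingredient_set(path: str | Path, format: str | None = None) -> list[Ingredient]:
    """Load ingredients from a wide CSV (one row per ingredient) or a JSON list.

    Empty amino-acid cells are recorded as absent, not zero.  The format is
    inferred from the file suffix unless given explicitly.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise SchemaError(f"{path}: expected a JSON list of ingredients")
        out = []
        for rec in records:
            out.append(Ingredient(name=str(rec["name"]),
                                  profile=NutrientProfile.from_dict(rec["profile"]),
                                  notes=str(rec.get("notes", ""))))
        as_ingredient_set(out)  # uniqueness check
        if not out:
            raise EmptyTableError(f"{path}: no ingredients")
        return out
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyTableError(f"{path}: empty file")
        missing = [c for c in _PROFILE_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        out = []
        for i, row in enumerate(reader):
            where = f"{path} row {i}"
            aa = {}
            for k in AMINO_ACIDS + tuple(AA_SUMS):
                cell = (row.get(k) or "").strip()
                if cell:
                    aa[k] = _parse_float(cell, f"{where} column {k}")
            try:
                profile = NutrientProfile(
                    protein_pct=_parse_float(row["protein_pct"], where),
                    fat_pct=_parse_float(row["fat_pct"], where),
                    ash_pct=_parse_float(row["ash_pct"], where),
                    fiber_pct=_parse_float(row["fiber_pct"], where),
                    carbohydrate_pct=_parse_float(row["carbohydrate_pct"], where),
                    energy_kcal=_parse_float(row["energy_kcal"], where),
                    moisture_pct=_parse_float(row.get("moisture_pct") or "0", where),
                    basis=(row.get("basis") or "dry").strip(),
                    amino_acids=aa,
                )
            except DataValidationError as exc:
                raise DataValidationError(f"{where}: {exc}") from None
            out.append(Ingredient(name=row["name"].strip(), profile=profile,
                                  notes=(row.get("notes") or "").strip()))
    as_ingredient_set(out)
    if not out:
        raise EmptyTableError(f"{path}: no ingredients")
    return out


def write_ingredient_set(ingredients: Iterable[Ingredient], path: str | Path,
                         format: str | None = None) -> None:
    """Write ingredients to CSV (wide) or JSON; round-trips with the loader."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    ingredients = list(ingredients)
    if fmt == "json":
        payload = [{"name": ing.name, "profile": ing.profile.to_dict(), "notes": ing.notes}
                   for ing in ingredients]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_PROFILE_COLUMNS + tuple(AA_SUMS))
        writer.writeheader()
        for ing in ingredients:
            p = ing.profile
            row = {"name": ing.name, "basis": p.basis, "notes": ing.notes,
                   "protein_pct": repr(p.protein_pct), "fat_pct": repr(p.fat_pct),
                   "ash_pct": repr(p.ash_pct), "fiber_pct": repr(p.fiber_pct),
                   "carbohydrate_pct": repr(p.carbohydrate_pct),
                   "energy_kcal": repr(p.energy_kcal), "moisture_pct": repr(p.moisture_pct)}
            for k in AMINO_ACIDS + tuple(AA_SUMS):
                if k in p.amino_acids:
                    row[k] = repr(p.amino_acids[k])
            writer.writerow(row)


def load_price_table(path: str | Path) -> PriceTable:
    """Load a long-format price CSV with columns ingredient, year, price_usd_per_kg."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyTableError(f"{path}: empty file")
        missing = [c for c in ("ingredient", "year", "price_usd_per_kg")
                   if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        entries: dict[tuple[str, int], float] = {}
        for i, row in enumerate(reader):
            where = f"{path} row {i}"
            ing = row["ingredient"].strip()
            year = int(_parse_float(row["year"], f"{where} column year"))
            if (ing, year) in entries:
                raise DataValidationError(f"{where}: duplicate price cell ({ing}, {year})")
            entries[(ing, year)] = _parse_float(
                row["price_usd_per_kg"], f"{where} column price_usd_per_kg")
    if not entries:
        raise EmptyTableError(f"{path}: no price rows")
    return PriceTable(entries)


def write_price_table(table: PriceTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ingredient", "year", "price_usd_per_kg"])
        for (ing, year) in sorted(table.entries):
            writer.writerow([ing, year, repr(table.entries[(ing, year)])])


def load_formulations(path: str | Path) -> list[Formulation]:
    """Load formulations from a long CSV with columns formulation, ingredient, percentage."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyTableError(f"{path}: empty file")
        missing = [c for c in ("formulation", "ingredient", "percentage")
                   if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        grouped: dict[str, dict[str, float]] = {}
        for i, row in enumerate(reader):
            name = row["formulation"].strip()
            ing = row["ingredient"].strip()
            pct = _parse_float(row["percentage"], f"{path} row {i}")
            comp = grouped.setdefault(name, {})
            if ing in comp:
                raise DataValidationError(
                    f"{path} row {i}: duplicate component {ing!r} in {name!r}")
            comp[ing] = pct
    if not grouped:
        raise EmptyTableError(f"{path}: no formulation rows")
    return [Formulation(name, comps) for name, comps in grouped.items()]


def load_requirement_set(path: str | Path) -> RequirementSet:
    """Load a daily requirement set from its JSON mirror."""
    return RequirementSet.from_dict(json.loads(Path(path).read_text()))
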