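"""Least-cost formulation linear program.

Decision variables are ingredient mass percentages x_i (0-100).  The model is

    minimize    sum_i (x_i / 100) * price_i          [USD per kg of blend]
    subject to  sum_i x_i = 100                      [mass balance]
                min_n <= sum_i (x_i/100) * a_{n,i} <= max_n   per nutrient n
                lo_i <= x_i <= hi_i                  per ingredient

where a_{n,i} is ingredient i's content of nutrient n per 100 g.  Fixed
inclusion levels (e.g. a koji grain at exactly 7%) are min = max box
constraints, so a product line with discrete level choices is a family of
separate LPs, not an integer program.

Solved with the HiGHS solver behind :func:`scipy.optimize.linprog`, which is
deterministic for a fixed input.  Optimal solutions are re-verified against
the constraint spec independently of the solver at tolerance 1e-6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import (
    DataValidationError,
    MissingPriceError,
    SchemaError,
    SolverError,
)
from .model import (
    Formulation,
    Ingredient,
    IngredientSet,
    PriceTable,
    RequirementSet,
    as_ingredient_set,
)

VERIFY_TOL = 1e-6  # external feasibility verification


@dataclass(frozen=True)
class ConstraintSpec:
    """Per-nutrient density bounds and per-ingredient inclusion bounds.

    ``nutrient_bounds`` maps a nutrient name to (min, max) per 100 g, either
    of which may be None.  ``ingredient_bounds`` maps an ingredient name to
    (min %, max %); min == max pins a fixed inclusion level.  Ingredients not
    mentioned default to (0, unbounded).
    """

    nutrient_bounds: Mapping[str, tuple[float | None, float | None]] = field(
        default_factory=dict)
    ingredient_bounds: Mapping[str, tuple[float, float | None]] = field(
        default_factory=dict)

    def __post_init__(self):
        for nut, (lo, hi) in dict(self.nutrient_bounds).items():
            if lo is not None and hi is not None and lo > hi:
                raise DataValidationError(f"nutrient {nut!r}: min {lo} > max {hi}")
        for ing, (lo, hi) in dict(self.ingredient_bounds).items():
            if lo < 0:
                raise DataValidationError(f"ingredient {ing!r}: min {lo} < 0")
            if hi is not None and lo > hi:
                raise DataValidationError(f"ingredient {ing!r}: min {lo} > max {hi}")
        object.__setattr__(self, "nutrient_bounds", dict(self.nutrient_bounds))
        object.__setattr__(self, "ingredient_bounds", dict(self.ingredient_bounds))

    def to_dict(self) -> dict:
        return {"nutrient_bounds": {k: {"min": v[0], "max": v[1]}
                                    for k, v in self.nutrient_bounds.items()},
                "ingredient_bounds": {k: {"min": v[0], "max": v[1]}
                                      for k, v in self.ingredient_bounds.items()}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConstraintSpec":
        nb = {k: (v.get("min"), v.get("max"))
              for k, v in dict(d.get("nutrient_bounds", {})).items()}
        ib = {k: (float(v.get("min") or 0.0),
                  None if v.get("max") is None else float(v["max"]))
              for k, v in dict(d.get("ingredient_bounds", {})).items()}
        return cls(nutrient_bounds=nb, ingredient_bounds=ib)


def load_constraint_spec(path) -> ConstraintSpec:
    """Read a ConstraintSpec from YAML or JSON."""
    import yaml

    with open(path) as fh:
        return ConstraintSpec.from_dict(yaml.safe_load(fh))


def requirement_to_density(req: RequirementSet, reference_energy_density: float,
                           mode: str = "energy") -> dict[str, float]:
    """Convert daily amounts to minimum densities per 100 g of product.

    ``mode="energy"`` scales each daily amount by the energy the product
    must deliver: min_n = req_n * reference_energy_density / energy_kcal_day.
    A product eaten in whatever quantity meets the daily energy requirement
    then automatically meets every scaled nutrient minimum.

    ``mode="per_protein"`` applies the amino-acid scoring-pattern convention
    instead: amino-acid minima are the requirement's AA:protein ratio times
    the energy-scaled protein minimum (macros are still energy-scaled).

    Returns a dict of minima including ``energy`` itself at the reference
    density.
    """
    if reference_energy_density <= 0:
        raise DataValidationError(
            f"reference_energy_density must be > 0, got {reference_energy_density}")
    if req.energy_kcal_day == 0:
        raise DataValidationError("energy requirement must be nonzero")
    scale = reference_energy_density / req.energy_kcal_day
    minima = {"energy": reference_energy_density,
              "protein": req.protein_g_day * scale,
              "carbohydrate": req.carbohydrate_g_day * scale,
              "fat": req.fat_g_day * scale}
    if mode == "energy":
        for k, v in req.amino_acids_g_day.items():
            minima[k] = v * scale
    elif mode == "per_protein":
        for k, v in req.amino_acids_g_day.items():
            minima[k] = (v / req.protein_g_day) * minima["protein"]
    else:
        raise ValueError(f"mode must be 'energy' or 'per_protein', got {mode!r}")
    return minima


def study_constraints(req: RequirementSet, koji: tuple[str, float],
                      aa_mode: str = "energy",
                      energy_floor: float = 452.0) -> ConstraintSpec:
    """The study's restriction set for one product.

    Fat capped at 20% (macronutrient distribution range), energy floored at
    452 kcal/100 g, sugar capped at 14%, amino-acid and protein minima from
    the daily requirements via :func:`requirement_to_density`, and the koji
    grain pinned at its fixed level with the other koji grain excluded.

    ``koji`` is ("rice", 7|14|21) or ("barley", 5|10|15).
    """
    grain, level = koji
    if grain not in ("rice", "barley"):
        raise DataValidationError(f"koji grain must be rice or barley, got {grain!r}")
    minima = requirement_to_density(req, energy_floor, mode=aa_mode)
    nutrient_bounds: dict[str, tuple[float | None, float | None]] = {
        "energy": (energy_floor, None),
        "fat": (None, 20.0),
        "protein": (minima["protein"], None),
    }
    for k in req.amino_acids_g_day:
        nutrient_bounds[k] = (minima[k], None)
    other = "barley" if grain == "rice" else "rice"
    ingredient_bounds = {"sugar": (0.0, 14.0),
                         grain: (float(level), float(level)),
                         other: (0.0, 0.0)}
    return ConstraintSpec(nutrient_bounds, ingredient_bounds)


@dataclass(frozen=True)
class LPProblem:
    """A fully assembled least-cost formulation instance."""

    ingredients: tuple[Ingredient, ...]
    prices: Mapping[str, float]           # USD/kg, one year
    constraints: ConstraintSpec
    # assembled arrays
    c: np.ndarray                         # objective coefficients (USD/kg per %)
    a_ub: np.ndarray                      # inequality rows
    b_ub: np.ndarray
    row_labels: tuple[str, ...]           # e.g. "fat:max", "energy:min"
    bounds: tuple[tuple[float, float | None], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ing.name for ing in self.ingredients)

    @property
    def n_equalities(self) -> int:
        return 1  # mass balance

    @property
    def n_inequalities(self) -> int:
        return len(self.row_labels)


def build_lp(ingredients: IngredientSet | Iterable[Ingredient],
             prices: Mapping[str, float],
             constraints: ConstraintSpec) -> LPProblem:
    """Assemble the LP arrays from profiles, prices and a constraint spec."""
    ingset = as_ingredient_set(ingredients)
    names = list(ingset)
    missing = [n for n in names if n not in prices]
    if missing:
        raise MissingPriceError(f"no price for ingredient(s): {missing}")
    bases = {ingset[n].profile.basis for n in names}
    if len(bases) > 1:
        from .errors import BasisError
        raise BasisError(f"mixed profile bases: {sorted(bases)}")
    c = np.array([prices[n] / 100.0 for n in names])
    rows, rhs, labels = [], [], []
    for nut, (lo, hi) in sorted(constraints.nutrient_bounds.items()):
        absent = [n for n in names if not ingset[n].profile.has_nutrient(nut)]
        if absent:
            raise SchemaError(
                f"constrained nutrient {nut!r} absent from profile(s): {absent}")
        coeff = np.array([ingset[n].profile.nutrient(nut) / 100.0 for n in names])
        if hi is not None:
            rows.append(coeff); rhs.append(hi); labels.append(f"{nut}:max")
        if lo is not None:
            rows.append(-coeff); rhs.append(-lo); labels.append(f"{nut}:min")
    unknown = sorted(set(constraints.ingredient_bounds) - set(names))
    if unknown:
        raise SchemaError(f"ingredient bound(s) for unknown ingredient(s): {unknown}")
    bounds = tuple(constraints.ingredient_bounds.get(n, (0.0, None)) for n in names)
    a_ub = np.array(rows) if rows else np.empty((0, len(names)))
    return LPProblem(ingredients=tuple(ingset.values()), prices=dict(prices),
                     constraints=constraints, c=c, a_ub=a_ub,
                     b_ub=np.array(rhs), row_labels=tuple(labels), bounds=bounds)


@dataclass(frozen=True)
class LPSolution:
    status: str                       # optimal | infeasible | unbounded
    formulation: Formulation | None
    cost_usd_per_kg: float | None
    binding_constraints: tuple[str, ...]
    solver_message: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "status": self.status,
            "formulation": None if self.formulation is None else self.formulation.to_dict(),
            "cost_usd_per_kg": self.cost_usd_per_kg,
            "binding_constraints": list(self.binding_constraints),
            "solver_message": self.solver_message,
        }, indent=1, sort_keys=True)


def solve_lp(p: LPProblem, name: str = "optimal") -> LPSolution:
    """Solve a least-cost instance with HiGHS and identify binding constraints.

    Binding constraints (slack below 1e-6) are reported by row label; pinned
    or saturated ingredient bounds appear as ``ingredient:min``/``:max``.
    """
    n = len(p.names)
    res = linprog(c=p.c, A_ub=p.a_ub if p.a_ub.size else None,
                  b_ub=p.b_ub if p.a_ub.size else None,
                  A_eq=np.ones((1, n)), b_eq=np.array([100.0]),
                  bounds=list(p.bounds), method="highs")
    if res.status == 2:
        return LPSolution("infeasible", None, None, (), res.message)
    if res.status == 3:
        return LPSolution("unbounded", None, None, (), res.message)
    if res.status != 0:
        raise SolverError(f"LP solver failure: {res.message}")
    x = np.clip(res.x, 0.0, None)
    binding = []
    if p.a_ub.size:
        slack = p.b_ub - p.a_ub @ x
        for lbl, s in zip(p.row_labels, slack):
            if abs(s) <= VERIFY_TOL * max(1.0, np.abs(p.b_ub).max()):
                binding.append(lbl)
    for i, (lo, hi) in enumerate(p.bounds):
        if hi is not None and abs(x[i] - hi) <= VERIFY_TOL:
            binding.append(f"{p.names[i]}:max")
        elif lo > 0 and abs(x[i] - lo) <= VERIFY_TOL:
            binding.append(f"{p.names[i]}:min")
    formulation = Formulation(name, {nm: float(v) for nm, v in zip(p.names, x)})
    cost = float(p.c @ x)
    return LPSolution("optimal", formulation, cost, tuple(binding), res.message)


def constraint_violations(f: Formulation,
                          ingredients: IngredientSet | Iterable[Ingredient],
                          constraints: ConstraintSpec,
                          tol: float = VERIFY_TOL) -> list[str]:
    """Check a candidate formulation against a constraint spec, solver-free.

    Returns human-readable descriptions of every violated bound (empty list
    when the candidate is feasible within ``tol``).  Useful both to verify
    solver output independently and to audit fixed published formulations.
    """
    ingset = as_ingredient_set(ingredients)
    out = []
    for nut, (lo, hi) in sorted(constraints.nutrient_bounds.items()):
        val = sum(pct / 100.0 * ingset[n].profile.nutrient(nut)
                  for n, pct in f.components.items())
        if lo is not None and val < lo - tol:
            out.append(f"{nut}={val:.4f} below min {lo}")
        if hi is not None and val > hi + tol:
            out.append(f"{nut}={val:.4f} above max {hi}")
    for ing, (lo, hi) in sorted(constraints.ingredient_bounds.items()):
        pct = f.components.get(ing, 0.0)
        if pct < lo - tol:
            out.append(f"{ing}={pct:.4f}% below min {lo}%")
        if hi is not None and pct > hi + tol:
            out.append(f"{ing}={pct:.4f}% above max {hi}%")
    total = f.total
    if abs(total - 100.0) > max(tol, 0.1):  # same slack as validate_formulation
        out.append(f"mass balance {total:.4f} != 100")
    return out


def formulate_series(ingredients: IngredientSet | Iterable[Ingredient],
                     price_table: PriceTable,
                     constraints: ConstraintSpec,
                     years: Sequence[int]) -> dict[int, LPSolution]:
    """One independent least-cost solve per year of the price series."""
    ingset = as_ingredient_set(ingredients)
    out: dict[int, LPSolution] = {}
    for year in years:
        try:
            prices = {n: price_table.price(n, year) for n in ingset}
            problem = build_lp(ingset, prices, constraints)
            out[year] = solve_lp(problem, name=f"optimal_{year}")
        except MissingPriceError as exc:
            raise MissingPriceError(f"year {year}: {exc}") from None
    return out
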