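"""Synthetic ingredient pools, price series, and LP instances with known optima.

Everything here is driven by :func:`numpy.random.default_rng` (PCG64), whose
bit stream is specified by NumPy independently of platform, so one seed
reproduces one pool everywhere.

Planted optima
--------------
:func:`plant_optimum` builds a least-cost instance whose unique optimum is a
blend you choose, by constructing an explicit dual certificate rather than
hoping: for a blend with k positive components it draws k-1 random nutrient
rows, sets those nutrient *minima exactly at the blend's own values* (so they
bind at the blend), and prices every ingredient as

    price_i = sum_j y_j * a_{j,i} + c0 (+ markup if the blend excludes i)

with positive dual weights y_j.  Complementary slackness then makes the blend
optimal, the strictly positive reduced cost (``markup``, scaled by the
``margin`` argument) forces every excluded ingredient to zero in any optimum,
and the random nutrient rows are almost surely independent, pinning the
support components uniquely.  Uniqueness is additionally certified against
the brute-force grid oracle when the instance is small enough to enumerate.

The oracle
----------
:func:`enumerate_oracle` exhaustively scans the percentage simplex on a fixed
grid (at most 3 free ingredients) and returns the cheapest feasible grid
point.  It shares no code with the LP path and serves as the independent
check on the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .blending import atwater_energy
from .errors import ComplexityError, DataValidationError, PlantingError
from .model import AMINO_ACIDS, Formulation, Ingredient, NutrientProfile, PriceTable, validate_formulation
from .lp import ConstraintSpec, LPProblem, LPSolution, build_lp

#: Nutrient slots used for planted constraints, in order of consumption.
_PLANT_NUTRIENTS = ("protein", "fat", "ash", "fiber") + AMINO_ACIDS

_PLANT_RANGES = {"protein": (5.0, 30.0), "fat": (2.0, 20.0), "ash": (0.5, 5.0),
                 "fiber": (1.0, 12.0)}
_AA_RANGE = (0.1, 2.5)

_DEFAULT_RANGES = {"protein": (2.0, 30.0), "fat": (0.5, 50.0),
                   "ash": (0.5, 5.0), "fiber": (1.0, 13.0)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic ingredient pool.

    Defaults emulate the Mali candidate list: 12 dry-basis commodities whose
    macros span common cereal/legume/oilseed ranges, prices between 0.06 and
    1.05 USD/kg (the span of the printed price table) drifting ~9% per year
    (the observed 2004-2009 trend), over six years.
    """

    n_ingredients: int = 12
    nutrient_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES))
    price_range: tuple[float, float] = (0.06, 1.05)
    price_drift: float = 0.09
    years: int = 6
    start_year: int = 2004
    seed: int = 0

    def __post_init__(self):
        if self.n_ingredients < 2:
            raise DataValidationError("need at least 2 ingredients")
        if self.years < 1:
            raise DataValidationError("need at least 1 year")
        for k, (lo, hi) in dict(self.nutrient_ranges).items():
            if lo > hi or lo < 0:
                raise DataValidationError(f"bad range for {k!r}: ({lo}, {hi})")
        lo, hi = self.price_range
        if not (0 < lo <= hi):
            raise DataValidationError(f"bad price range ({lo}, {hi})")
        object.__setattr__(self, "nutrient_ranges", dict(self.nutrient_ranges))


def generate_pool(spec: SyntheticSpec) -> tuple[list[Ingredient], PriceTable]:
    """Draw a reproducible ingredient pool and multiplicatively drifting prices.

    Macros are uniform within their ranges, rescaled if needed so that
    protein + fat + ash + fiber <= 99, with carbohydrate filling the
    remainder to 100 (dry basis) and energy from the 4/9/4 factors.
    """
    rng = np.random.default_rng(spec.seed)
    macro_keys = ("protein", "fat", "ash", "fiber")
    aa_keys = tuple(k for k in spec.nutrient_ranges if k in AMINO_ACIDS)
    ingredients = []
    for i in range(spec.n_ingredients):
        draws = {}
        for k in macro_keys:
            lo, hi = spec.nutrient_ranges.get(k, _DEFAULT_RANGES[k])
            draws[k] = rng.uniform(lo, hi)
        total = sum(draws.values())
        if total > 99.0:
            draws = {k: v * 99.0 / total for k, v in draws.items()}
        carb = 100.0 - sum(draws.values())
        aa = {}
        for k in aa_keys:
            lo, hi = spec.nutrient_ranges[k]
            aa[k] = rng.uniform(lo, hi)
        profile = NutrientProfile(
            protein_pct=draws["protein"], fat_pct=draws["fat"], ash_pct=draws["ash"],
            fiber_pct=draws["fiber"], carbohydrate_pct=carb,
            energy_kcal=atwater_energy(draws["protein"], draws["fat"], carb),
            basis="dry", amino_acids=aa)
        ingredients.append(Ingredient(name=f"ing{i:02d}", profile=profile,
                                      notes="synthetic"))
    entries = {}
    base = rng.uniform(*spec.price_range, size=spec.n_ingredients)
    for i, ing in enumerate(ingredients):
        for k in range(spec.years):
            entries[(ing.name, spec.start_year + k)] = float(
                base[i] * (1.0 + spec.price_drift) ** k)
    return ingredients, PriceTable(entries)


def plant_optimum(blend: Formulation, margin: float, seed: int = 0,
                  certify: bool | None = None, step: float = 0.1) -> LPProblem:
    """Construct an LP instance whose unique optimum is ``blend``.

    ``margin`` scales the reduced-cost markup (USD/kg per unit margin) priced
    onto every ingredient the blend excludes; ``margin <= 0`` produces a
    degenerate face (alternative optima possible) and only warns.
    ``certify`` controls oracle certification of uniqueness at resolution
    ``step`` (default: certify automatically when <= 3 ingredients).
    """
    validate_formulation(blend)
    names = list(blend.components)
    support = [n for n in names if blend.components[n] > 0]
    k = len(support)
    if k - 1 > len(_PLANT_NUTRIENTS):
        raise PlantingError(f"support of size {k} needs more nutrient slots than exist")
    degenerate = margin <= 0
    if degenerate:
        warnings.warn("margin <= 0: planted optimum lies on a degenerate face; "
                      "uniqueness not guaranteed", UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    nutrients = _PLANT_NUTRIENTS[:max(k - 1, 0)]
    n = len(names)
    a = np.zeros((len(nutrients), n))
    for j, nut in enumerate(nutrients):
        lo, hi = _PLANT_RANGES.get(nut, _AA_RANGE)
        a[j] = rng.uniform(lo, hi, size=n)
    y = rng.uniform(0.004, 0.02, size=len(nutrients))
    c0 = float(rng.uniform(0.1, 0.3))
    markup = 0.0 if degenerate else 0.01 * float(margin)
    b = np.array([blend.components[nm] / 100.0 for nm in names])
    prices = {}
    for i, nm in enumerate(names):
        prices[nm] = float(y @ a[:, i] + c0 + (0.0 if blend.components[nm] > 0 else markup))
    minima = a @ b  # binding at the planted blend by construction

    ingredients = []
    for i, nm in enumerate(names):
        draws = {nut: float(a[j, i]) for j, nut in enumerate(nutrients)}
        macro = {key: draws.get(key, {"protein": 10.0, "fat": 5.0, "ash": 1.0,
                                      "fiber": 2.0}[key])
                 for key in ("protein", "fat", "ash", "fiber")}
        carb = 100.0 - sum(macro.values())
        aa = {key: v for key, v in draws.items() if key in AMINO_ACIDS}
        ingredients.append(Ingredient(
            name=nm, notes="synthetic (planted)",
            profile=NutrientProfile(
                protein_pct=macro["protein"], fat_pct=macro["fat"],
                ash_pct=macro["ash"], fiber_pct=macro["fiber"],
                carbohydrate_pct=carb,
                energy_kcal=atwater_energy(macro["protein"], macro["fat"], carb),
                basis="dry", amino_acids=aa)))
    spec = ConstraintSpec(
        nutrient_bounds={nut: (float(minima[j]), None) for j, nut in enumerate(nutrients)})
    problem = build_lp(ingredients, prices, spec)
    if certify is None:
        certify = (not degenerate) and n <= 3
    if certify:
        if n > 3:
            raise ComplexityError("cannot certify uniqueness with more than 3 free ingredients")
        _certify_unique(problem, blend, step)
    return problem


def _certify_unique(problem: LPProblem, blend: Formulation, step: float) -> None:
    """Raise PlantingError unless the oracle's near-optimal set is the blend alone."""
    x, packed, names = _oracle_grid(problem, step)
    if x is None:
        raise PlantingError("planted instance has over-committed fixed levels")
    ok, cost = packed
    if not ok.any():
        raise PlantingError("planted instance enumerates as infeasible")
    near = np.flatnonzero(cost <= cost.min() + 1e-9)
    target = np.array([blend.components.get(nm, 0.0) for nm in names])
    dev = np.abs(x[near] - target).max(axis=1)
    if len(near) != 1 or dev.max() > step / 2:
        raise PlantingError(
            f"uniqueness certification failed: {len(near)} near-optimal grid points, "
            f"max deviation {dev.max():.3f}")


def _simplex_grid(t: int, f: int) -> np.ndarray:
    """All f-part compositions of t, lexicographic, as an (npoints, f) int array."""
    if f == 1:
        return np.array([[t]])
    if f == 2:
        i = np.arange(t + 1)
        return np.stack([i, t - i], axis=1)
    ii = np.repeat(np.arange(t + 1), np.arange(t + 1, 0, -1))
    jj = np.concatenate([np.arange(t - i + 1) for i in range(t + 1)])
    return np.stack([ii, jj, t - ii - jj], axis=1)


def _oracle_grid(problem: LPProblem, step: float):
    """Shared grid construction: returns (X, (feasible_mask-applied costs), names)."""
    if abs(round(100.0 / step) - 100.0 / step) > 1e-9:
        raise DataValidationError(f"step {step} does not divide 100")
    names = list(problem.names)
    n = len(names)
    lows = np.array([lo for lo, _ in problem.bounds])
    highs = np.array([np.inf if hi is None else hi for _, hi in problem.bounds])
    fixed = lows == highs
    free_idx = np.flatnonzero(~fixed)
    if len(free_idx) > 3:
        raise ComplexityError(
            f"{len(free_idx)} free ingredients; the oracle enumerates at most 3")
    remainder = 100.0 - lows[fixed].sum()
    t_float = remainder / step
    if abs(round(t_float) - t_float) > 1e-9:
        raise DataValidationError(
            f"fixed levels leave {remainder}%, not a multiple of step {step}")
    t = int(round(t_float))
    if t < 0:
        return None, None, names
    grid = _simplex_grid(t, len(free_idx)) * step if len(free_idx) else np.zeros((1, 0))
    x = np.tile(lows * fixed, (len(grid), 1))
    x[:, free_idx] = grid
    ok = np.ones(len(x), dtype=bool)
    ok &= (x[:, free_idx] >= lows[free_idx] - 1e-9).all(axis=1)
    ok &= (x[:, free_idx] <= highs[free_idx] + 1e-9).all(axis=1)
    if problem.a_ub.size:
        ok &= (x @ problem.a_ub.T <= problem.b_ub + 1e-9).all(axis=1)
    cost = x @ problem.c
    cost = np.where(ok, cost, np.inf)
    return x, (ok, cost), names


def enumerate_oracle(p: LPProblem, step: float = 0.1) -> LPSolution:
    """Best feasible grid point of the percentage simplex, by exhaustive scan.

    Ingredients whose bounds pin them (min == max) are held fixed; at most 3
    ingredients may remain free.  ``step`` (percent) must divide 100.  The
    scan is lexicographic, so ties resolve deterministically to the first
    grid point.
    """
    x, packed, names = _oracle_grid(p, step)
    if x is None:
        return LPSolution("infeasible", None, None, (), "fixed levels exceed 100%")
    ok, cost = packed
    if not ok.any():
        return LPSolution("infeasible", None, None, (), "no feasible grid point")
    best = int(np.argmin(cost))
    formulation = Formulation("oracle", {nm: float(v) for nm, v in zip(names, x[best])})
    return LPSolution("optimal", formulation, float(cost[best]), (),
                      f"grid scan at step {step}")


def random_feasible_points(problem: LPProblem, n: int, seed: int = 0,
                           anchor: Formulation | None = None,
                           max_draws: int = 200_000) -> np.ndarray:
    """Up to ``n`` random feasible percentage vectors of ``problem``.

    Draws Dirichlet points on the simplex (respecting fixed levels), mixed
    toward ``anchor`` when given (an anchor known feasible — e.g. a planted
    blend — makes the feasible region easy to hit).  Used for weak-duality
    smoke tests: every returned point's cost upper-bounds the optimum.
    """
    rng = np.random.default_rng(seed)
    names = list(problem.names)
    lows = np.array([lo for lo, _ in problem.bounds])
    highs = np.array([np.inf if hi is None else hi for _, hi in problem.bounds])
    fixed = lows == highs
    free_idx = np.flatnonzero(~fixed)
    if len(free_idx) == 0:
        return np.tile(lows, (1, 1))
    remainder = 100.0 - lows[fixed].sum()
    target = (np.array([anchor.components.get(nm, 0.0) for nm in names])
              if anchor is not None else None)
    out = []
    batch = max(n * 10, 1000)
    drawn = 0
    while len(out) < n and drawn < max_draws:
        pts = np.tile(lows * fixed, (batch, 1))
        pts[:, free_idx] = rng.dirichlet(np.ones(len(free_idx)), size=batch) * remainder
        if target is not None:
            u = rng.uniform(0, 1, size=(batch, 1))
            pts = u * pts + (1 - u) * target
        ok = (pts[:, free_idx] >= lows[free_idx] - 1e-12).all(axis=1)
        ok &= (pts[:, free_idx] <= highs[free_idx] + 1e-12).all(axis=1)
        if problem.a_ub.size:
            ok &= (pts @ problem.a_ub.T <= problem.b_ub + 1e-12).all(axis=1)
        out.extend(pts[ok])
        drawn += batch
    return np.array(out[:n])
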