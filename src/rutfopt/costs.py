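"""Ingredient-cost arithmetic for fixed formulations across a price series.

The cost of 1 kg of blend is the percentage-weighted mean of ingredient
prices: sum_i (pct_i / 100) * price_i, in USD/kg.  Costs are ingredient-only
(no processing, packaging or yield correction).  The trend table mirrors the
published layout: years as rows, formulations as columns, mean +/- sample SD
across formulations as the final column, and the first-to-last-year change.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataValidationError, MissingPriceError
from .model import Formulation, PriceTable, validate_formulation


def formulation_cost(f: Formulation, prices: Mapping[str, float]) -> float:
    """Ingredient cost of 1 kg of the blend (USD/kg) at the given prices."""
    missing = sorted(set(f.components) - set(prices))
    if missing:
        raise MissingPriceError(f"formulation {f.name!r}: no price for {missing}")
    return sum(pct / 100.0 * prices[ing] for ing, pct in f.components.items())


@dataclass(frozen=True)
class CostTrendTable:
    """Formulation x year cost matrix with yearly summaries and period change."""

    costs: Mapping[tuple[str, int], float]       # (formulation, year) -> USD/kg
    yearly_mean: Mapping[int, float]
    yearly_sd: Mapping[int, float | None]        # sample SD; None when < 2 formulations
    period_change: Mapping[str, float]           # last year - first year, unrounded
    formulations: tuple[str, ...]
    years: tuple[int, ...]

    def rounded_mean_change(self, ndigits: int = 2) -> float:
        """First-to-last change of the *rounded* yearly means.

        Published period changes are differences of the displayed (rounded)
        yearly figures, which can differ from rounding the exact change.
        """
        first, last = self.years[0], self.years[-1]
        return round(self.yearly_mean[last], ndigits) - round(self.yearly_mean[first], ndigits)

    def to_frame(self) -> pd.DataFrame:
        """Years as rows, formulations as columns, mean/sd appended."""
        data = {f: [self.costs[(f, y)] for y in self.years] for f in self.formulations}
        frame = pd.DataFrame(data, index=list(self.years))
        frame.index.name = "year"
        frame["mean"] = [self.yearly_mean[y] for y in self.years]
        frame["sd"] = [self.yearly_sd[y] for y in self.years]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_cost_trend(formulations: Sequence[Formulation], price_table: PriceTable,
                     years: Sequence[int]) -> CostTrendTable:
    """Cost every formulation in every year and summarize.

    Every (ingredient, year) price must be present; a missing cell raises
    :class:`MissingPriceError` naming it — prices are never interpolated.
    """
    if not formulations or not years:
        raise DataValidationError("need at least one formulation and one year")
    for f in formulations:
        validate_formulation(f)
    years = tuple(int(y) for y in years)
    names = tuple(f.name for f in formulations)
    if len(set(names)) != len(names):
        raise DataValidationError("duplicate formulation names")
    costs: dict[tuple[str, int], float] = {}
    for year in years:
        for f in formulations:
            prices = {}
            for ing in f.components:
                prices[ing] = price_table.price(ing, year)  # raises with cell name
            costs[(f.name, year)] = formulation_cost(f, prices)
    yearly_mean = {y: statistics.fmean(costs[(n, y)] for n in names) for y in years}
    yearly_sd = {y: (statistics.stdev([costs[(n, y)] for n in names])
                     if len(names) > 1 else None) for y in years}
    period_change = {n: costs[(n, years[-1])] - costs[(n, years[0])] for n in names}
    return CostTrendTable(costs=costs, yearly_mean=yearly_mean, yearly_sd=yearly_sd,
                          period_change=period_change, formulations=names, years=years)
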