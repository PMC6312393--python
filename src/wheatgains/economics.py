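"""Producer benefits, benefit-cost ratios, consumer rations, and surplus.

Everything runs in real 2016 USD on the published annual series: area sown
to program varieties by wheat type (ha), price per metric ton, and program
costs.  Producer benefits value the cumulative genetic gain on the area
actually sown:

    benefit_t = sum_types area_{i,t} * g_i(t) / 1000 * P_t

(gain in kg/ha, price per ton, hence the /1000).  Rations divide the extra
kilograms by an annual per-capita consumption (60.9 kg for South Africa).
The economic-surplus calculation converts a proportional supply shift K
into consumer and producer surplus changes, in two variants:

* ``parallel-alston`` — the textbook parallel-shift model: with price
  reduction Z = K*eps/(eps+eta), dCS = P*Q*Z*(1 + 0.5*Z*eta) and
  dPS = P*Q*(K-Z)*(1 + 0.5*Z*eta), so producers gain whenever K >= Z.
* ``incidence`` — keeps dCS as above but allocates producers a loss
  in fixed proportion dPS = -dCS*eta/eps, reproducing evaluations in which
  consumers gain more than producers lose and dCS/|dPS| = eps/eta for
  every year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ECON_TYPES
from .genetic_gain import GainSeries

VARIANTS = ("parallel-alston", "incidence")


class EconError(ValueError):
    """Invalid economic computation request."""


class GainCoverageError(EconError):
    """A gain series does not cover the economic years requested."""


@dataclass(frozen=True)
class SurplusParams:
    """Economic-surplus parameters.

    Elasticities are absolute values (demand elasticity 0.22 means -0.22);
    ``supply_shift`` is the proportional vertical supply shift K attributed
    to the breeding program; ``per_capita_consumption`` is kg/person/year;
    ``discount_rate`` is the annual rate used for benefit-cost discounting.
    """

    demand_elasticity: float = 0.22
    supply_elasticity: float = 0.68
    supply_shift: float = 0.0051
    variant: str = "incidence"
    per_capita_consumption: float = 60.9
    discount_rate: float = 0.1025

    def __post_init__(self) -> None:
        if self.demand_elasticity <= 0 or self.supply_elasticity <= 0:
            raise EconError("elasticities must be positive (absolute values)")
        if not 0.0 <= self.supply_shift < 1.0:
            raise EconError("supply shift K must lie in [0, 1)")
        if self.discount_rate < 0:
            raise EconError("discount rate must be non-negative")
        if self.variant not in VARIANTS:
            raise EconError(f"variant must be one of {VARIANTS}")
        if self.per_capita_consumption <= 0:
            raise EconError("per-capita consumption must be positive")


def _gain_for_years(series: GainSeries, years: pd.Index, label: str) -> np.ndarray:
    """Cumulative gain aligned to ``years``; zero before the first release."""
    beyond = [int(y) for y in years if y > series.horizon]
    if beyond:
        raise GainCoverageError(
            f"{label}: gain series ends {series.horizon}, missing years {beyond}"
        )
    return np.array([series.gain_at(int(y)) for y in years])


@dataclass(frozen=True)
class BenefitResult:
    """Per-year producer benefits (2016 USD) by wheat type, with totals."""

    per_year: pd.DataFrame  # columns: one per type + "total"
    total: float
    average: float


def producer_benefits(
    econ: pd.DataFrame, gains: dict[str, GainSeries]
) -> BenefitResult:
    """Value the genetic gain on the area sown, at the year's real price.

    ``econ`` must carry ``area_<type>_ha`` columns for every key of
    ``gains`` and a ``price_2016usd_per_ton`` column; years before a type's
    first release contribute nothing.
    """
    years = econ.index
    price = econ["price_2016usd_per_ton"].to_numpy(float)
    out = pd.DataFrame(index=years)
    for wtype, series in gains.items():
        col = f"area_{wtype}_ha"
        if col not in econ.columns:
            raise EconError(f"economic series lacks column {col!r}")
        g = _gain_for_years(series, years, wtype)
        out[wtype] = econ[col].to_numpy(float) * g / 1000.0 * price
    out["total"] = out.sum(axis=1)
    return BenefitResult(
        per_year=out,
        total=float(out["total"].sum()),
        average=float(out["total"].mean()),
    )


def additional_production_kg(
    econ: pd.DataFrame, gains: dict[str, GainSeries]
) -> pd.Series:
    """Extra kilograms of wheat per year: area times cumulative gain, summed over types."""
    years = econ.index
    total = np.zeros(len(years))
    for wtype, series in gains.items():
        col = f"area_{wtype}_ha"
        if col not in econ.columns:
            raise EconError(f"economic series lacks column {col!r}")
        total += econ[col].to_numpy(float) * _gain_for_years(series, years, wtype)
    return pd.Series(total, index=years, name="additional_kg")


def benefit_cost_ratio(
    benefits: pd.Series,
    costs: pd.Series,
    r: float = 0.0,
    base_year: int | None = None,
) -> float:
    """Discounted benefit-cost ratio: sum B_t/(1+r)^t over sum C_t/(1+r)^t.

    Exponents count years from ``base_year`` (default: first year of the
    series).  ``r = 0`` gives the plain ratio of totals.
    """
    if r < 0:
        raise EconError("discount rate must be non-negative")
    idx = benefits.index.intersection(costs.index)
    if len(idx) == 0:
        raise EconError("benefit and cost series share no years")
    if base_year is None:
        base_year = int(idx.min())
    disc = (1.0 + r) ** -(idx.to_numpy(float) - base_year)
    num = float((benefits.loc[idx].to_numpy(float) * disc).sum())
    den = float((costs.loc[idx].to_numpy(float) * disc).sum())
    if den == 0:
        raise EconError("discounted costs are zero; ratio undefined")
    return num / den


@dataclass(frozen=True)
class RationResult:
    """Additional annual wheat rations implied by extra production."""

    annual: pd.Series  # unrounded rations per year
    rounded: pd.Series  # whole rations for display
    average: float
    total: float


def rations(additional_kg: pd.Series, per_capita: float = 60.9) -> RationResult:
    """Convert extra kilograms per year into per-person annual rations."""
    if per_capita <= 0:
        raise EconError("per-capita consumption must be positive")
    annual = additional_kg / per_capita
    annual.name = "rations"
    return RationResult(
        annual=annual,
        rounded=annual.round().astype("int64"),
        average=float(annual.mean()),
        total=float(annual.sum()),
    )


@dataclass(frozen=True)
class SurplusChange:
    consumer: float
    producer: float

    @property
    def net(self) -> float:
        return self.consumer + self.producer


def surplus(P: float, Q: float, params: SurplusParams) -> SurplusChange:
    """Consumer/producer surplus change from a proportional supply shift.

    ``P`` is the price (2016 USD/ton) and ``Q`` the total market quantity
    (tons) in the year.  See the module docstring for the two variants.
    """
    if P <= 0 or Q <= 0:
        raise EconError("price and quantity must be positive")
    eta = params.demand_elasticity
    eps = params.supply_elasticity
    K = params.supply_shift
    if eps + eta == 0:
        raise EconError("supply and demand elasticities sum to zero")
    Z = K * eps / (eps + eta)
    dCS = P * Q * Z * (1.0 + 0.5 * Z * eta)
    if params.variant == "parallel-alston":
        dPS = P * Q * (K - Z) * (1.0 + 0.5 * Z * eta)
    else:  # incidence
        dPS = -dCS * eta / eps
    return SurplusChange(consumer=dCS, producer=dPS)


def surplus_series(
    prices: pd.Series, quantities: pd.Series, params: SurplusParams
) -> pd.DataFrame:
    """Per-year surplus decomposition for aligned price/quantity series."""
    idx = prices.index.intersection(quantities.index)
    rows = []
    for year in idx:
        s = surplus(float(prices.loc[year]), float(quantities.loc[year]), params)
        rows.append(
            {
                "year": int(year),
                "consumer_surplus": s.consumer,
                "producer_surplus": s.producer,
                "net_surplus": s.net,
            }
        )
    return pd.DataFrame(rows).set_index("year")


def consumer_table(
    econ: pd.DataFrame,
    gains: dict[str, GainSeries],
    params: SurplusParams,
    production_tons: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-year consumer-side summary: extra kg, rations, and (optionally) surplus.

    Surplus dollars require the national production series ``Q``; when it
    is not supplied only the physical quantities are reported.
    """
    addkg = additional_production_kg(econ, gains)
    r = rations(addkg, params.per_capita_consumption)
    out = pd.DataFrame(
        {"additional_kg": addkg, "additional_rations": r.rounded}
    )
    if production_tons is not None:
        s = surplus_series(econ["price_2016usd_per_ton"], production_tons, params)
        out = out.join(s)
    return out


__all__ = [
    "ECON_TYPES",
    "SurplusParams",
    "BenefitResult",
    "RationResult",
    "SurplusChange",
    "producer_benefits",
    "additional_production_kg",
    "benefit_cost_ratio",
    "rations",
    "surplus",
    "surplus_series",
    "consumer_table",
    "EconError",
    "GainCoverageError",
]
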