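"""Cumulative genetic-gain series from a fitted vintage coefficient.

A vintage coefficient ``beta1`` (kg/ha per unit log vintage index) converts
into a calendar series of cumulative yield gains over the first release of
the wheat type:

    g(t) = beta1 * ln(t - y0 + 1),   t = y0, ..., horizon

so the first release year contributes ln(1) = 0 and increments shrink as
the program ages (log concavity).  With the published winter coefficient of
163 kg/ha the second program year carries ln(2)*163 = 112.98 kg/ha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class GainError(ValueError):
    """Invalid gain-series request."""


@dataclass(frozen=True)
class GainSeries:
    """Cumulative genetic gain (kg/ha) per calendar year for one wheat type."""

    wheat_type: str
    beta1: float
    y0: int
    values: pd.Series  # index: calendar year; values: cumulative kg/ha

    @property
    def horizon(self) -> int:
        return int(self.values.index.max())

    @property
    def terminal(self) -> float:
        """Cumulative gain in the final year of the series."""
        return float(self.values.iloc[-1])

    def gain_at(self, year: int) -> float:
        """Cumulative gain for one calendar year; 0 for years before ``y0``."""
        if year < self.y0:
            return 0.0
        if year > self.horizon:
            raise GainError(
                f"{self.wheat_type}: year {year} beyond series horizon "
                f"{self.horizon}"
            )
        return float(self.values.loc[year])


def cumulative_gain(
    beta1: float, y0: int, horizon_year: int, wheat_type: str = ""
) -> GainSeries:
    """Cumulative gain series g(t) = beta1 * ln(t - y0 + 1) on [y0, horizon]."""
    if not np.isfinite(beta1):
        raise GainError("beta1 must be finite")
    if horizon_year < y0:
        raise GainError(
            f"horizon {horizon_year} precedes first release year {y0}"
        )
    years = np.arange(y0, horizon_year + 1)
    vals = beta1 * np.log(years - y0 + 1)
    return GainSeries(
        wheat_type=wheat_type,
        beta1=float(beta1),
        y0=int(y0),
        values=pd.Series(vals, index=pd.Index(years, name="year")),
    )


def annual_average_gain(series: GainSeries, T: int | None = None) -> float:
    """Average annual gain: terminal cumulative gain divided by ``T`` years.

    ``T`` defaults to the series length (horizon - y0 + 1).  It is exposed
    because published annualizations are not always consistent about
    whether the release year itself counts as a program year.
    """
    if len(series.values) < 2:
        raise GainError("series must span at least two years")
    if T is None:
        T = series.horizon - series.y0 + 1
    if T < 1:
        raise GainError("T must be a positive number of years")
    return series.terminal / T


@dataclass(frozen=True)
class PercentGain:
    total_pct: float
    annual_pct: float


def percent_gain(
    series: GainSeries, base_mean_yield: float, T: int | None = None
) -> PercentGain:
    """Terminal gain as a percentage of the base variety's mean yield.

    ``base_mean_yield`` is the observed mean yield (kg/ha) of the wheat
    type's first release(s); the annual percentage divides the total by
    ``T`` (defaulting to the series length).
    """
    if not base_mean_yield > 0:
        raise GainError("base mean yield must be positive")
    if T is None:
        T = series.horizon - series.y0 + 1
    total = 100.0 * series.terminal / base_mean_yield
    return PercentGain(total_pct=total, annual_pct=total / T)


def gain_table(series: dict[str, GainSeries], decimals: int = 2) -> pd.DataFrame:
    """Year-by-type table of cumulative gains, rounded for display.

    Years before a type's first release are left missing, matching the
    published presentation; internal arithmetic is never rounded.
    """
    cols = {name: s.values for name, s in series.items()}
    out = pd.DataFrame(cols)
    out.index.name = "year"
    return out.round(decimals)
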