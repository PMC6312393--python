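"""Packaged published-series fixtures: variety summaries, areas, prices, costs.

These small CSVs transcribe the published summary tables of the ARC wheat
breeding program evaluation — the per-variety descriptive statistics, the
annual area sown to program varieties by wheat type with real 2016 USD
prices, the annual program costs, and the published per-type regression
coefficients.  They are the *inputs* to the downstream gain/benefit
arithmetic; the raw 25,690-row trial dataset itself was never deposited and
is emulated by :mod:`wheatgains.synthetic_trials`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .trial_data import VarietyRecord, build_registry

#: Wheat-type keys used for the per-type economic series and gain series.
ECON_TYPES = ("spring_irrigated", "winter", "facultative")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("wheatgains.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_variety_summary() -> pd.DataFrame:
    """Published per-variety summary: release year, type, yield moments, % irrigated."""
    return _read("variety_summary.csv")


def load_reference_registry() -> dict[str, VarietyRecord]:
    """Variety registry (name, release year, wheat type) for the 26 released varieties."""
    vs = load_variety_summary()
    return build_registry(vs[["variety", "release_year", "wheat_type"]])


def load_econ_series() -> pd.DataFrame:
    """Annual area sown to program varieties by type (ha) and prices, 1992-2015.

    Indexed by calendar year; columns ``area_<type>_ha`` for each of
    :data:`ECON_TYPES` plus nominal and real 2016 USD prices per metric ton.
    """
    return _read("econ_series.csv").set_index("year")


def load_program_costs() -> pd.Series:
    """Annual breeding-program costs in 2016 USD, 1992-2015 (year-indexed)."""
    df = _read("program_costs.csv").set_index("year")
    return df["cost_2016usd"]


def load_reference_coefficients() -> pd.DataFrame:
    """Published per-type regression results (OLS yield, variance, FGLS yield).

    Indexed by wheat type (winter, spring_irrigated, spring_dryland,
    facultative), with the first release year of each type and the mean
    yield of its first release(s) used as the base for percentage gains.
    """
    df = _read("reference_coefficients.csv").set_index("wheat_type")
    for col in ("ols_stars", "jp_variance_stars", "jp_yield_stars"):
        df[col] = df[col].fillna("")
    return df
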