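"""Variety-trial panel containers, validation, and release-year encoding.

A *panel* is an unbalanced collection of plot-level yield records from a
multi-environment variety-trial network (here, the South African ARC wheat
trials: replicated randomized-block trials on producers' fields, planted in
either an optimal or a late window, under irrigated or dryland management).
Each variety carries the calendar year it was released to the public; the
release year, re-encoded as an ordinal index from the first release of its
wheat type, is the "vintage" regressor of the yield and yield-variance
models downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

WHEAT_TYPES = ("winter", "facultative", "spring")

#: Columns a panel CSV must provide, in canonical order.
PANEL_COLUMNS = [
    "plot_id",
    "region",
    "trial_year",
    "variety",
    "yield_kg_ha",
    "planting",
    "irrigated",
    "replicate",
]

REGISTRY_COLUMNS = ["variety", "release_year", "wheat_type"]

_MAX_REPORTED_ROWS = 10


class PanelError(ValueError):
    """Base class for panel construction problems."""


class SchemaError(PanelError):
    """A required column is missing from an input file."""


class RegistryError(PanelError):
    """An observation references a variety absent from the registry."""


class ValidationError(PanelError):
    """Row-level values violate the panel invariants."""


@dataclass(frozen=True)
class VarietyRecord:
    """One released variety: name, vintage, and wheat type.

    ``first_release_of_type`` is the calendar year of the earliest release
    of the same wheat type in the registry; it anchors the ordinal vintage
    index (the first release of a type has index 1).
    """

    name: str
    release_year: int
    wheat_type: str
    first_release_of_type: int

    def __post_init__(self) -> None:
        if self.wheat_type not in WHEAT_TYPES:
            raise ValidationError(
                f"variety {self.name!r}: wheat_type {self.wheat_type!r} "
                f"not one of {WHEAT_TYPES}"
            )
        if self.release_year < self.first_release_of_type:
            raise ValidationError(
                f"variety {self.name!r}: release year {self.release_year} "
                f"predates first release of its type "
                f"({self.first_release_of_type})"
            )


def release_index(variety: VarietyRecord) -> int:
    """Ordinal vintage index of a variety: 1 for the first release of its type.

    The log of this index (``LNRLYR``) is the vintage regressor in both the
    mean and variance equations, so the first release of each wheat type
    contributes ln(1) = 0.
    """
    idx = variety.release_year - variety.first_release_of_type + 1
    if idx < 1:
        raise ValidationError(
            f"variety {variety.name!r}: release index {idx} < 1"
        )
    return idx


def log_release_index(variety: VarietyRecord) -> float:
    """``LNRLYR`` for a variety: natural log of its vintage index."""
    return math.log(release_index(variety))


@dataclass(frozen=True)
class TrialObservation:
    """One replicate-level yield record from a variety trial.

    ``planting`` is 1 for the optimal planting window and 0 for late
    planting; ``irrigated`` is 1 under irrigation and 0 for dryland.
    """

    plot_id: str
    region: str
    trial_year: int
    variety: str
    yield_kg_ha: float
    planting: int
    irrigated: int
    replicate: int


def build_registry(frame: pd.DataFrame) -> dict[str, VarietyRecord]:
    """Build a name -> :class:`VarietyRecord` mapping from a registry table.

    ``first_release_of_type`` is computed per wheat type as the minimum
    release year present in the table.
    """
    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"registry is missing columns: {missing}")
    dupes = frame["variety"][frame["variety"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate varieties in registry: {sorted(set(dupes))}")
    first = frame.groupby("wheat_type")["release_year"].min()
    registry: dict[str, VarietyRecord] = {}
    for row in frame.itertuples(index=False):
        registry[str(row.variety)] = VarietyRecord(
            name=str(row.variety),
            release_year=int(row.release_year),
            wheat_type=str(row.wheat_type),
            first_release_of_type=int(first[row.wheat_type]),
        )
    return registry


def load_registry(path) -> dict[str, VarietyRecord]:
    """Read a variety registry CSV (columns: variety, release_year, wheat_type)."""
    return build_registry(pd.read_csv(path))


def _report_rows(label: str, rows: Iterable[int], detail: pd.Series | None = None) -> str:
    rows = list(rows)
    shown = rows[:_MAX_REPORTED_ROWS]
    msgs = []
    for r in shown:
        extra = f" ({detail.loc[r]})" if detail is not None else ""
        msgs.append(f"row {r}{extra}")
    more = f" ... and {len(rows) - len(shown)} more" if len(rows) > len(shown) else ""
    return f"{label}: {', '.join(msgs)}{more}"


class Panel:
    """A validated variety-trial panel: observations plus a variety registry.

    Observations live in a :class:`pandas.DataFrame` with the columns of
    :data:`PANEL_COLUMNS`; every variety must exist in the registry, yields
    must be finite and non-negative, planting/irrigated must be 0/1 binary
    flags, and replicate-level records must be unique on
    (plot_id, trial_year, variety, replicate).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        registry: Mapping[str, VarietyRecord],
        year_range: tuple[int, int] | None = None,
    ) -> None:
        self.registry = dict(registry)
        self.year_range = year_range
        self.frame = self._validate(frame)

    # -- validation ------------------------------------------------------

    def _validate(self, frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"panel is missing columns: {missing}")
        frame = frame[PANEL_COLUMNS].copy()
        frame = frame.reset_index(drop=True)

        unknown = ~frame["variety"].isin(self.registry.keys())
        if unknown.any():
            raise RegistryError(
                _report_rows(
                    "unknown variety", frame.index[unknown], frame["variety"]
                )
            )

        y = pd.to_numeric(frame["yield_kg_ha"], errors="coerce")
        bad_yield = ~np.isfinite(y) | (y < 0)
        if bad_yield.any():
            raise ValidationError(
                _report_rows(
                    "yield must be finite and non-negative",
                    frame.index[bad_yield],
                    frame["yield_kg_ha"],
                )
            )
        frame["yield_kg_ha"] = y.astype(float)

        for col in ("planting", "irrigated"):
            v = pd.to_numeric(frame[col], errors="coerce")
            bad = ~v.isin([0, 1])
            if bad.any():
                raise ValidationError(
                    _report_rows(f"{col} must be 0/1", frame.index[bad], frame[col])
                )
            frame[col] = v.astype(int)

        rep = pd.to_numeric(frame["replicate"], errors="coerce")
        bad_rep = ~np.isfinite(rep) | (rep < 1) | (rep != rep.round())
        if bad_rep.any():
            raise ValidationError(
                _report_rows(
                    "replicate must be a positive integer",
                    frame.index[bad_rep],
                    frame["replicate"],
                )
            )
        frame["replicate"] = rep.astype(int)
        frame["trial_year"] = pd.to_numeric(frame["trial_year"]).astype(int)
        frame["plot_id"] = frame["plot_id"].astype(str)
        frame["region"] = frame["region"].astype(str)
        frame["variety"] = frame["variety"].astype(str)

        if self.year_range is not None:
            lo, hi = self.year_range
            bad_yr = (frame["trial_year"] < lo) | (frame["trial_year"] > hi)
            if bad_yr.any():
                raise ValidationError(
                    _report_rows(
                        f"trial_year outside [{lo}, {hi}]",
                        frame.index[bad_yr],
                        frame["trial_year"],
                    )
                )

        # replicate-level records: duplicates are rejected, not averaged
        key = ["plot_id", "trial_year", "variety", "replicate"]
        dup = frame.duplicated(subset=key)
        if dup.any():
            raise ValidationError(
                _report_rows("duplicate (plot, year, variety, replicate)",
                             frame.index[dup], frame["variety"])
            )

        # no observation may predate the variety's release
        ry = frame["variety"].map(lambda v: self.registry[v].release_year)
        early = frame["trial_year"] < ry
        if early.any():
            raise ValidationError(
                _report_rows(
                    "observation predates the variety's release year",
                    frame.index[early],
                    frame["variety"],
                )
            )
        return frame

    # -- views -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def observations(self) -> list[TrialObservation]:
        """The records as typed objects (row order preserved)."""
        return [
            TrialObservation(*row)
            for row in self.frame[PANEL_COLUMNS].itertuples(index=False)
        ]

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def metadata(self) -> dict:
        """Tallies by wheat type, irrigation, and planting window."""
        wt = self.frame["variety"].map(lambda v: self.registry[v].wheat_type)
        return {
            "n_obs": int(len(self.frame)),
            "n_plots": int(self.frame["plot_id"].nunique()),
            "n_varieties": int(self.frame["variety"].nunique()),
            "by_type": wt.value_counts().to_dict(),
            "n_irrigated": int(self.frame["irrigated"].sum()),
            "n_late": int((self.frame["planting"] == 0).sum()),
            "years": (int(self.frame["trial_year"].min()),
                      int(self.frame["trial_year"].max()))
            if len(self.frame)
            else None,
        }

    def design_frame(self) -> pd.DataFrame:
        """Observations augmented with wheat_type and LNRLYR columns."""
        out = self.frame.copy()
        out["wheat_type"] = out["variety"].map(
            lambda v: self.registry[v].wheat_type
        )
        lnr = {name: log_release_index(rec) for name, rec in self.registry.items()}
        out["lnrlyr"] = out["variety"].map(lnr)
        return out

    def subset(
        self, wheat_type: str | None = None, irrigated: int | None = None
    ) -> "Panel":
        """Sub-panel restricted to one wheat type and/or irrigation status."""
        mask = pd.Series(True, index=self.frame.index)
        if wheat_type is not None:
            wt = self.frame["variety"].map(
                lambda v: self.registry[v].wheat_type
            )
            mask &= wt == wheat_type
        if irrigated is not None:
            mask &= self.frame["irrigated"] == irrigated
        sub = Panel.__new__(Panel)
        sub.registry = self.registry
        sub.year_range = self.year_range
        sub.frame = self.frame[mask].reset_index(drop=True)
        return sub

    # -- io ----------------------------------------------------------------

    def save(self, path) -> None:
        """Write the observations to CSV (registry is saved separately)."""
        self.frame.to_csv(path, index=False)

    def save_registry(self, path) -> None:
        rows = [
            {"variety": r.name, "release_year": r.release_year,
             "wheat_type": r.wheat_type}
            for r in self.registry.values()
        ]
        pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, index=False)


def load_panel(path, registry_path) -> Panel:
    """Read and validate a trial panel CSV against a variety-registry CSV.

    Row order is preserved; any invalid row aborts the load with a message
    naming the offending rows.
    """
    registry = load_registry(registry_path)
    # round_trip parsing keeps save -> load -> save a fixed point at the ulp
    frame = pd.read_csv(path, float_precision="round_trip")
    return Panel(frame, registry)


def descriptive_stats(panel: Panel, baseline_variety: str) -> pd.DataFrame:
    """Per-variety yield summary relative to a baseline variety.

    Returns one row per variety with observation count, mean and SD of
    yield, CV%, the yield ratio and difference against the baseline's mean,
    and the percentage of irrigated observations.  Varieties with no
    observations are dropped with a warning.
    """
    if baseline_variety not in panel.registry:
        raise RegistryError(f"baseline variety {baseline_variety!r} not in registry")
    frame = panel.frame
    grouped = frame.groupby("variety")["yield_kg_ha"]
    if baseline_variety not in grouped.groups:
        raise ValidationError(
            f"baseline variety {baseline_variety!r} has no observations"
        )
    base_mean = grouped.get_group(baseline_variety).mean()

    absent = [v for v in panel.registry if v not in grouped.groups]
    if absent:
        warnings.warn(
            f"varieties with no observations excluded from summary: {sorted(absent)}",
            stacklevel=2,
        )

    rows = []
    for name, values in grouped:
        rec = panel.registry[name]
        mean = values.mean()
        sd = values.std(ddof=1) if len(values) > 1 else np.nan
        irr = frame.loc[frame["variety"] == name, "irrigated"].mean() * 100.0
        rows.append(
            {
                "variety": name,
                "release_year": rec.release_year,
                "wheat_type": rec.wheat_type,
                "n_obs": int(len(values)),
                "mean_yield_kg_ha": mean,
                "sd_yield_kg_ha": sd,
                "cv_pct": 100.0 * sd / mean if mean > 0 else np.nan,
                "yield_ratio": mean / base_mean,
                "yield_diff_kg_ha": mean - base_mean,
                "pct_irrigated": irr,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["release_year", "variety"], kind="stable"
    )
    return out.reset_index(drop=True)
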