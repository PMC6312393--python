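"""Synthetic variety-trial panels from the Just-Pope data-generating process.

The raw trial dataset behind the published analysis (25,690 usable plot-level
yields from 125 locations, 1998-2014) was never deposited, so this module
generates unbalanced panels from the same mean/variance structure the
estimator assumes:

    Y    = b0 + b1*ln(idx) + b2*PLANTING + type/irrigation shifts
           + year effect + plot effect + e
    e ~ Normal(0, exp(a0 + a1*ln(idx) + a2*PLANTING + irrigation shift
                      + variance year effect + variance plot effect))

where ``idx`` is the ordinal vintage index of the variety (1 = first release
of its wheat type).  Varieties enter trials with a configurable lag after
release and persist to a configurable exit age, which produces the entry/exit
unbalance of real multi-environment trial networks.  Yields are drawn on the
kg/ha scale and truncated at zero (with the truncation count recorded);
parameter regimes used in tests keep truncation negligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .trial_data import Panel, VarietyRecord, build_registry

REGIONS = ("free_state_dryland", "western_cape", "free_state_irrigated")

#: Late-planting share of the real dataset: 10,949 of 25,690 usable records.
LATE_FRACTION = 10949 / 25690

#: Usable records in the study panel vs the sum of per-variety counts in the
#: published descriptive table; used to scale per-type sampling targets.
USABLE_OBS = 25690
SUMMARY_OBS_TOTAL = 36507


class ConfigError(ValueError):
    """Invalid data-generating-process configuration."""


@dataclass
class DGPConfig:
    """Parameters of the Just-Pope data-generating process.

    Mean equation (kg/ha): ``beta0`` intercept, ``beta1`` per unit LNRLYR,
    ``beta2`` optimal-planting effect (PLANTING = 1 optimal, 0 late),
    ``beta_irrigated`` irrigation shift, ``type_effects`` additive mean
    shift per wheat type.  Variance equation (log kg^2/ha^2 scale):
    ``alpha0/alpha1/alpha2/alpha_irrigated`` analogous.  Year and plot fixed
    effects may be supplied explicitly; when left ``None`` they are drawn
    Normal(0, sd) deterministically from ``seed`` so the realized truth is
    reproducible for recovery tests.
    """

    release_schedule: list[tuple[str, int, str]]  # (variety, release_year, type)
    beta0: float = 2300.0
    beta1: float = 163.0
    beta2: float = 400.0
    beta_irrigated: float = 3100.0
    type_effects: dict[str, float] = field(default_factory=dict)
    alpha0: float = 14.0
    alpha1: float = 0.12
    alpha2: float = -0.2
    alpha_irrigated: float = 0.7
    year_effects: dict[int, float] | None = None
    plot_effects: dict[str, float] | None = None
    variance_year_effects: dict[int, float] | None = None
    variance_plot_effects: dict[str, float] | None = None
    year_effect_sd: float = 400.0
    plot_effect_sd: float = 600.0
    variance_year_effect_sd: float = 0.4
    variance_plot_effect_sd: float = 0.4
    n_plots: int = 125
    year_range: tuple[int, int] = (1998, 2014)
    replicates: int = 4
    late_fraction: float = LATE_FRACTION
    irrigated_fraction_by_type: dict[str, float] = field(default_factory=dict)
    inclusion_prob_by_type: dict[str, float] = field(default_factory=dict)
    entry_lag: int = 1
    exit_age: int | None = None
    noiseless: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.release_schedule:
            raise ConfigError("release schedule is empty")
        if not 0.0 <= self.late_fraction <= 1.0:
            raise ConfigError("late_fraction must lie in [0, 1]")
        for t, f in self.irrigated_fraction_by_type.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"irrigated fraction for {t!r} outside [0, 1]")
        for t, p in self.inclusion_prob_by_type.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"inclusion probability for {t!r} outside [0, 1]")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError("year_range start exceeds end")
        if self.n_plots < 1:
            raise ConfigError("n_plots must be >= 1")

    def plot_ids(self) -> list[str]:
        return [f"P{i:03d}" for i in range(1, self.n_plots + 1)]

    def years(self) -> list[int]:
        return list(range(self.year_range[0], self.year_range[1] + 1))

    def first_release(self) -> dict[str, int]:
        first: dict[str, int] = {}
        for _, ry, wt in self.release_schedule:
            first[wt] = min(first.get(wt, ry), ry)
        return first

    def active_years(self, release_year: int) -> list[int]:
        """Trial years in which a variety of the given vintage appears."""
        start = max(self.year_range[0], release_year + self.entry_lag)
        end = self.year_range[1]
        if self.exit_age is not None:
            end = min(end, release_year + self.exit_age)
        return list(range(start, end + 1))


@dataclass(frozen=True)
class RealizedEffects:
    """Fixed-effect truth realized for one configuration (drawn or supplied)."""

    year: dict[int, float]
    plot: dict[str, float]
    variance_year: dict[int, float]
    variance_plot: dict[str, float]


def realized_effects(config: DGPConfig) -> RealizedEffects:
    """Year/plot fixed effects in force for ``config``.

    Effects left unset are drawn Normal(0, sd) from a generator derived
    solely from ``config.seed``, so repeated calls (and
    :func:`simulate_panel`) see identical values.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 11])
    years = config.years()
    plots = config.plot_ids()
    draws = {
        "year": dict(zip(years, rng.normal(0.0, config.year_effect_sd, len(years)))),
        "plot": dict(zip(plots, rng.normal(0.0, config.plot_effect_sd, len(plots)))),
        "variance_year": dict(
            zip(years, rng.normal(0.0, config.variance_year_effect_sd, len(years)))
        ),
        "variance_plot": dict(
            zip(plots, rng.normal(0.0, config.variance_plot_effect_sd, len(plots)))
        ),
    }
    return RealizedEffects(
        year=config.year_effects if config.year_effects is not None else draws["year"],
        plot=config.plot_effects if config.plot_effects is not None else draws["plot"],
        variance_year=config.variance_year_effects
        if config.variance_year_effects is not None
        else draws["variance_year"],
        variance_plot=config.variance_plot_effects
        if config.variance_plot_effects is not None
        else draws["variance_plot"],
    )


def expected_yield(
    config: DGPConfig,
    *,
    release_idx: int,
    planting: int = 1,
    irrigated: int = 0,
    wheat_type: str | None = None,
    year_effect: float = 0.0,
    plot_effect: float = 0.0,
) -> float:
    """Population mean yield for one covariate cell under the DGP."""
    wt_shift = config.type_effects.get(wheat_type, 0.0) if wheat_type else 0.0
    return (
        config.beta0
        + config.beta1 * math.log(release_idx)
        + config.beta2 * planting
        + config.beta_irrigated * irrigated
        + wt_shift
        + year_effect
        + plot_effect
    )


def simulate_panel(config: DGPConfig) -> Panel:
    """Draw one unbalanced trial panel from the configured Just-Pope DGP.

    The same configuration and seed always produce an identical panel.  The
    returned :class:`~wheatgains.trial_data.Panel` carries the number of
    zero-truncated yields as ``panel.n_truncated``.
    """
    config.validate()
    effects = realized_effects(config)
    rng = np.random.default_rng([int(config.seed) % (2**31), 22])

    plots = np.array(config.plot_ids())
    region_of = {p: REGIONS[i % len(REGIONS)] for i, p in enumerate(plots)}
    plot_eff = np.array([effects.plot[p] for p in plots])
    vplot_eff = np.array([effects.variance_plot[p] for p in plots])
    first = config.first_release()

    never = [v for v, ry, _ in config.release_schedule if not config.active_years(ry)]
    if never:
        warnings.warn(
            f"varieties never trialled under the entry/exit rule: {never}",
            stacklevel=2,
        )

    # Enumerate candidate cells (variety x active year x plot) in a fixed
    # order so the random stream, hence the panel, is reproducible.
    cell_frames = []
    for vi, (name, ry, wt) in enumerate(config.release_schedule):
        yrs = config.active_years(ry)
        if not yrs:
            continue
        yrs = np.array(yrs)
        n_cells = len(yrs) * len(plots)
        cell_frames.append(
            pd.DataFrame(
                {
                    "variety": name,
                    "wheat_type": wt,
                    "lnrlyr": math.log(ry - first[wt] + 1),
                    "trial_year": np.repeat(yrs, len(plots)),
                    "plot_i": np.tile(np.arange(len(plots)), len(yrs)),
                }
            )
        )
    cells = pd.concat(cell_frames, ignore_index=True)

    p_incl = cells["wheat_type"].map(
        lambda t: config.inclusion_prob_by_type.get(t, 1.0)
    ).to_numpy()
    p_irr = cells["wheat_type"].map(
        lambda t: config.irrigated_fraction_by_type.get(t, 0.0)
    ).to_numpy()

    keep = rng.random(len(cells)) < p_incl
    late = rng.random(len(cells)) < config.late_fraction
    irr = rng.random(len(cells)) < p_irr

    cells = cells.loc[keep].reset_index(drop=True)
    planting = (~late[keep]).astype(int)  # 1 = optimal window
    irrigated = irr[keep].astype(int)

    year_eff = cells["trial_year"].map(effects.year).to_numpy()
    vyear_eff = cells["trial_year"].map(effects.variance_year).to_numpy()
    type_shift = cells["wheat_type"].map(
        lambda t: config.type_effects.get(t, 0.0)
    ).to_numpy()

    mu = (
        config.beta0
        + config.beta1 * cells["lnrlyr"].to_numpy()
        + config.beta2 * planting
        + config.beta_irrigated * irrigated
        + type_shift
        + year_eff
        + plot_eff[cells["plot_i"]]
    )
    logvar = (
        config.alpha0
        + config.alpha1 * cells["lnrlyr"].to_numpy()
        + config.alpha2 * planting
        + config.alpha_irrigated * irrigated
        + vyear_eff
        + vplot_eff[cells["plot_i"]]
    )
    if not np.all(np.isfinite(logvar)):
        raise ConfigError("variance coefficients give non-finite log-variance")
    sd = 0.0 if config.noiseless else np.exp(0.5 * logvar)

    z = rng.standard_normal((len(cells), config.replicates))
    y = mu[:, None] + (sd[:, None] if np.ndim(sd) else sd) * z
    n_truncated = int((y < 0).sum())
    y = np.maximum(y, 0.0)

    reps = config.replicates
    frame = pd.DataFrame(
        {
            "plot_id": np.repeat(plots[cells["plot_i"]], reps),
            "region": np.repeat(
                cells["plot_i"].map(lambda i: region_of[plots[i]]).to_numpy(), reps
            ),
            "trial_year": np.repeat(cells["trial_year"].to_numpy(), reps),
            "variety": np.repeat(cells["variety"].to_numpy(), reps),
            "yield_kg_ha": y.ravel(),
            "planting": np.repeat(planting, reps),
            "irrigated": np.repeat(irrigated, reps),
            "replicate": np.tile(np.arange(1, reps + 1), len(cells)),
        }
    )
    registry = build_registry(
        pd.DataFrame(
            config.release_schedule,
            columns=["variety", "release_year", "wheat_type"],
        )
    )
    panel = Panel(frame, registry, year_range=config.year_range)
    panel.n_truncated = n_truncated
    return panel


def _schedule_from_summary(summary: pd.DataFrame) -> list[tuple[str, int, str]]:
    return [
        (str(r.variety), int(r.release_year), str(r.wheat_type))
        for r in summary.itertuples(index=False)
    ]


def study_scale_config(seed: int = 0) -> DGPConfig:
    """Default configuration emulating the scale of the real study panel.

    125 plots over trial years 1998-2014 with four-replicate trials, the 26
    released varieties with their published release years and types, the
    observed late-planting share (10,949/25,690), per-type irrigated shares
    from the published descriptive table, and per-type inclusion
    probabilities chosen so expected observation counts match the published
    per-variety counts scaled to the 25,690 usable records.
    """
    summary = datasets.load_variety_summary()
    cfg = DGPConfig(
        release_schedule=_schedule_from_summary(summary),
        type_effects={"winter": 0.0, "facultative": 60.0, "spring": 800.0},
        seed=seed,
    )
    obs_w = summary["n_obs"].to_numpy(dtype=float)
    irr_frac = (
        summary.assign(w=obs_w * summary["pct_irrigated"] / 100.0)
        .groupby("wheat_type")
        .apply(lambda g: g["w"].sum() / g["n_obs"].sum(), include_groups=False)
    )
    cfg.irrigated_fraction_by_type = irr_frac.to_dict()

    scale = USABLE_OBS / SUMMARY_OBS_TOTAL
    target = summary.groupby("wheat_type")["n_obs"].sum() * scale
    candidates: dict[str, int] = {}
    for _, ry, wt in cfg.release_schedule:
        candidates[wt] = candidates.get(wt, 0) + len(cfg.active_years(ry)) * cfg.n_plots * cfg.replicates
    cfg.inclusion_prob_by_type = {
        wt: min(1.0, float(target[wt]) / candidates[wt]) for wt in candidates
    }
    return cfg


def winter_panel_config(seed: int = 0) -> DGPConfig:
    """Winter-wheat-only configuration at roughly the study's winter scale.

    Thirty dryland plots, 1998-2014, the five published winter releases,
    and an inclusion probability targeting ~4,300 observations — the size
    of the winter sub-panel the published winter coefficients (vintage
    effect 163 kg/ha, variance slope 0.12) were estimated on.  Used for
    parameter-recovery simulation studies, so the noise scale is kept mild
    enough that zero-truncation of yields stays below ~0.1% and cannot
    bias the estimator being checked (the full-scale
    :func:`study_scale_config` keeps the study's much larger dispersion).
    """
    summary = datasets.load_variety_summary()
    winter = summary[summary["wheat_type"] == "winter"]
    cfg = DGPConfig(
        release_schedule=_schedule_from_summary(winter),
        beta0=3200.0,
        beta1=163.0,
        alpha0=12.4,
        alpha1=0.12,
        type_effects={"winter": 0.0},
        irrigated_fraction_by_type={"winter": 0.0},
        year_effect_sd=300.0,
        plot_effect_sd=400.0,
        variance_year_effect_sd=0.3,
        variance_plot_effect_sd=0.3,
        n_plots=30,
        seed=seed,
    )
    candidates = sum(
        len(cfg.active_years(ry)) * cfg.n_plots * cfg.replicates
        for _, ry, _ in cfg.release_schedule
    )
    cfg.inclusion_prob_by_type = {"winter": min(1.0, 4287 / candidates)}
    return cfg


def homoscedastic(config: DGPConfig) -> DGPConfig:
    """Copy of ``config`` with a constant error variance (null DGP).

    Sets the variance slopes and the variance fixed-effect spreads to zero
    while keeping the mean structure; useful for equal-weights limit checks.
    """
    return replace(
        config,
        alpha1=0.0,
        alpha2=0.0,
        alpha_irrigated=0.0,
        variance_year_effect_sd=0.0,
        variance_plot_effect_sd=0.0,
        variance_year_effects=None,
        variance_plot_effects=None,
    )
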