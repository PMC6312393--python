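"""End-to-end orchestration: panel -> fits -> gain series -> economics -> reports.

The pipeline either simulates a panel from a Just-Pope DGP configuration or
loads one from CSV, fits the four per-type mean/variance models, converts
vintage coefficients into cumulative gain series, and values the gains on
the published area/price/cost series.  Each stage's output is written as a
CSV shaped like the corresponding published table, plus a JSON run log
recording the seed, a configuration hash, and every design setting in
force.  Runs are deterministic: the same configuration and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, datasets, economics, genetic_gain, justpope
from .economics import SurplusParams
from .synthetic_trials import DGPConfig, study_scale_config, simulate_panel
from .trial_data import Panel, descriptive_stats, load_panel


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of {``simulate``, (``panel_path`` and ``registry_path``)}
    selects the panel source.  ``coefficient_source`` chooses whether the
    gain/benefit stages use the vintage coefficients fitted on the panel
    ("fitted") or the published reference coefficients ("reference").
    """

    outdir: str = "wheatgains_out"
    simulate: bool = True
    dgp: DGPConfig | None = None
    panel_path: str | None = None
    registry_path: str | None = None
    coefficient_source: str = "reference"  # reference | fitted
    horizon: int = 2015
    baseline_variety: str = "TUGELA-DN"
    surplus: SurplusParams = field(default_factory=SurplusParams)
    discount_rates: tuple[float, ...] = (0.0, 0.1025)
    seed: int = 0

    def validate(self) -> None:
        has_files = self.panel_path is not None and self.registry_path is not None
        if self.simulate == has_files:
            raise ValueError(
                "exactly one of simulate=True or panel_path+registry_path "
                "must be active"
            )
        if self.coefficient_source not in ("reference", "fitted"):
            raise ValueError("coefficient_source must be 'reference' or 'fitted'")


@dataclass
class ReportBundle:
    """In-memory results plus the paths of every file written."""

    outdir: Path
    panel: Panel
    fits: dict[str, justpope.JustPopeFit]
    gains: dict[str, genetic_gain.GainSeries]
    benefits: economics.BenefitResult
    bcr: pd.DataFrame
    consumer: pd.DataFrame
    paths: dict[str, Path]


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return run
    return wrap


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@_stage("panel")
def _get_panel(config: RunConfig) -> Panel:
    if config.simulate:
        dgp = config.dgp if config.dgp is not None else study_scale_config(config.seed)
        return simulate_panel(dgp)
    return load_panel(config.panel_path, config.registry_path)


@_stage("fit")
def _fit_models(panel: Panel) -> dict[str, justpope.JustPopeFit]:
    fits = {}
    for name, spec in justpope.default_specs().items():
        fits[name] = justpope.fit_fgls(panel, spec)
    return fits


@_stage("gains")
def _gain_series(
    config: RunConfig, fits: dict[str, justpope.JustPopeFit]
) -> dict[str, genetic_gain.GainSeries]:
    ref = datasets.load_reference_coefficients()
    gains = {}
    for wtype in datasets.ECON_TYPES:
        if config.coefficient_source == "reference":
            beta1 = float(ref.loc[wtype, "jp_yield"])
        else:
            beta1 = float(fits[wtype].mean_fgls.loc["lnrlyr", "estimate"])
        y0 = int(ref.loc[wtype, "first_release_year"])
        gains[wtype] = genetic_gain.cumulative_gain(
            beta1, y0, config.horizon, wheat_type=wtype
        )
    return gains


@_stage("economics")
def _economics(
    config: RunConfig, gains: dict[str, genetic_gain.GainSeries]
) -> tuple[economics.BenefitResult, pd.DataFrame, pd.DataFrame]:
    econ = datasets.load_econ_series()
    econ = econ.loc[econ.index <= config.horizon]
    costs = datasets.load_program_costs()
    benefits = economics.producer_benefits(econ, gains)
    bcr_rows = [
        {
            "discount_rate": r,
            "bcr": economics.benefit_cost_ratio(
                benefits.per_year["total"], costs, r=r
            ),
        }
        for r in config.discount_rates
    ]
    consumer = economics.consumer_table(econ, gains, config.surplus)
    return benefits, pd.DataFrame(bcr_rows), consumer


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    panel = _get_panel(config)
    paths["panel"] = outdir / "panel.csv"
    panel.save(paths["panel"])
    paths["registry"] = outdir / "registry.csv"
    panel.save_registry(paths["registry"])

    try:
        stats = descriptive_stats(panel, config.baseline_variety)
    except Exception as exc:  # baseline may be absent in custom panels
        raise PipelineError("descriptives", exc) from exc
    paths["descriptives"] = outdir / "descriptives.csv"
    stats.round(2).to_csv(paths["descriptives"], index=False)

    fits = _fit_models(panel)
    paths["fit_report"] = outdir / "fit_report.csv"
    justpope.fit_report(fits).round(4).to_csv(paths["fit_report"], index=False)
    paths["coefficients"] = outdir / "coefficients_full.csv"
    justpope.full_coefficients(fits).round(6).to_csv(
        paths["coefficients"], index=False
    )

    gains = _gain_series(config, fits)
    paths["gains"] = outdir / "gains.csv"
    genetic_gain.gain_table(gains).to_csv(paths["gains"])

    benefits, bcr, consumer = _economics(config, gains)
    paths["benefits"] = outdir / "benefits.csv"
    per_year = benefits.per_year.round(2)
    per_year.to_csv(paths["benefits"])
    paths["bcr"] = outdir / "bcr.csv"
    bcr.round(4).to_csv(paths["bcr"], index=False)
    paths["consumer"] = outdir / "consumer.csv"
    consumer.round(2).to_csv(paths["consumer"])

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": _jsonable(config),
        "settings": {
            "cluster_scheme": {
                name: spec.cluster
                for name, spec in justpope.default_specs().items()
            },
            "resid_floor_quantile": justpope.ModelSpec("x").resid_floor_quantile,
            "fgls_iterations": justpope.ModelSpec("x").fgls_iterations,
            "surplus_variant": config.surplus.variant,
            "n_truncated_yields": getattr(panel, "n_truncated", None),
        },
        "panel_metadata": panel.metadata,
        "benefit_total_2016usd": benefits.total,
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))

    return ReportBundle(
        outdir=outdir,
        panel=panel,
        fits=fits,
        gains=gains,
        benefits=benefits,
        bcr=bcr,
        consumer=consumer,
        paths=paths,
    )
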