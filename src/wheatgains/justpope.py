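"""Just-Pope mean/variance estimation by OLS and feasible GLS.

The mean equation regresses plot-level yield on the log vintage index
(LNRLYR), a planting-window indicator, optionally an irrigation indicator,
and trial-year and plot fixed effects.  The variance equation regresses the
log squared mean-equation residuals on the same covariate structure; its
fitted values define observation weights 1/exp(fitted log-variance) for a
reweighted (FGLS) mean fit.  Inference is cluster-robust; the default
scheme clusters on the trial-year x production-region interaction, with a
two-way year/region option.

The least-squares solves are delegated to :mod:`statsmodels`; the two-stage
procedure, residual flooring, and the clustered sandwich covariance are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

from .trial_data import Panel


class FitError(ValueError):
    """Estimation cannot proceed on the given panel/spec."""


class RankDeficiencyError(FitError):
    """The design matrix is collinear; names the offending columns."""


class ClusterError(FitError):
    """Clustering scheme is degenerate (fewer than two clusters)."""


class DegenerateVarianceError(FitError):
    """All mean-equation residuals are zero; no variance equation exists."""


def significance_stars(p: float) -> str:
    """Conventional significance stars: *** 0.01, ** 0.05, * 0.10."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


@dataclass
class ModelSpec:
    """One per-wheat-type model specification.

    ``wheat_type`` filters the panel ("spring" combined with the
    ``irrigated`` filter gives the spring-irrigated / spring-dryland
    sub-models).  ``include_irrigated_regressor`` adds the 0/1 irrigation
    indicator to both equations (only meaningful when the filtered panel
    mixes both management systems).
    """

    name: str
    wheat_type: str | None = None
    irrigated: int | None = None
    include_irrigated_regressor: bool = False
    fe_year: bool = True
    fe_plot: bool = True
    cluster: str = "year_region"  # year_region | twoway | year | region | none
    resid_floor_quantile: float = 0.01
    fgls_iterations: int = 1
    extra_regressors: tuple[str, ...] = ()


def default_specs() -> dict[str, ModelSpec]:
    """The four published per-type model specifications."""
    return {
        "winter": ModelSpec("winter", wheat_type="winter"),
        "spring_irrigated": ModelSpec(
            "spring_irrigated", wheat_type="spring", irrigated=1
        ),
        "spring_dryland": ModelSpec(
            "spring_dryland", wheat_type="spring", irrigated=0
        ),
        "facultative": ModelSpec("facultative", wheat_type="facultative"),
    }


@dataclass
class Design:
    """Materialized regression design for one spec."""

    y: np.ndarray
    X: pd.DataFrame
    clusters: dict[str, np.ndarray]  # scheme component -> integer codes
    base_year: int
    base_plot: str
    n_obs: int

    @property
    def matrix(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


@dataclass
class JustPopeFit:
    """Coefficient tables and diagnostics for one wheat-type fit.

    ``mean_ols``, ``variance`` and ``mean_fgls`` are indexed by term with
    columns estimate / se / t / pvalue / stars; SEs and p-values use the
    cluster-robust covariance of the spec (degrees of freedom = clusters-1).
    """

    name: str
    n_obs: int
    mean_yield: float
    mean_ols: pd.DataFrame
    r2_ols: float
    ols_residuals: np.ndarray
    design: Design
    spec: ModelSpec
    variance: pd.DataFrame | None = None
    fitted_log_variance: np.ndarray | None = None
    n_floored: int = 0
    mean_fgls: pd.DataFrame | None = None
    r2_fgls: float | None = None
    weights: np.ndarray | None = None
    weight_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design construction


def build_design(panel: Panel, spec: ModelSpec) -> Design:
    """Filter the panel per spec and build the fixed-effects design matrix."""
    df = panel.design_frame()
    if spec.wheat_type is not None:
        df = df[df["wheat_type"] == spec.wheat_type]
    if spec.irrigated is not None:
        df = df[df["irrigated"] == spec.irrigated]
    if df.empty:
        raise FitError(f"{spec.name}: no observations after filtering")
    df = df.reset_index(drop=True)

    if df["lnrlyr"].nunique() < 2:
        raise FitError(
            f"{spec.name}: needs >= 2 distinct release indices, "
            f"found {df['lnrlyr'].nunique()}"
        )

    cols: dict[str, np.ndarray] = {
        "const": np.ones(len(df)),
        "lnrlyr": df["lnrlyr"].to_numpy(float),
        "planting": df["planting"].to_numpy(float),
    }
    if spec.include_irrigated_regressor:
        cols["irrigated"] = df["irrigated"].to_numpy(float)
    for name in spec.extra_regressors:
        cols[name] = df[name].to_numpy(float)

    X = pd.DataFrame(cols, index=df.index)
    base_year = int(df["trial_year"].min())
    base_plot = str(sorted(df["plot_id"].unique())[0])
    if spec.fe_year:
        d = pd.get_dummies(df["trial_year"], prefix="year", dtype=float)
        X = pd.concat([X, d.drop(columns=f"year_{base_year}")], axis=1)
    if spec.fe_plot:
        d = pd.get_dummies(df["plot_id"], prefix="plot", dtype=float)
        X = pd.concat([X, d.drop(columns=f"plot_{base_plot}")], axis=1)

    _check_rank(X, spec)

    yr = df["trial_year"].to_numpy()
    region = df["region"].to_numpy()
    clusters = {
        "year": pd.factorize(yr)[0],
        "region": pd.factorize(region)[0],
        "year_region": pd.factorize(
            pd.Series(yr.astype(str)) + "|" + pd.Series(region)
        )[0],
    }
    return Design(
        y=df["yield_kg_ha"].to_numpy(float),
        X=X,
        clusters=clusters,
        base_year=base_year,
        base_plot=base_plot,
        n_obs=len(df),
    )


def _check_rank(X: pd.DataFrame, spec: ModelSpec) -> None:
    M = X.to_numpy(float)
    # scale columns so the pivoted-QR tolerance is meaningful across units
    norms = np.linalg.norm(M, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = scipy.linalg.qr(M / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    zero_cols = [X.columns[i] for i, nrm in enumerate(np.linalg.norm(M, axis=0)) if nrm == 0]
    bad = sorted(set(bad) | set(zero_cols))
    if bad:
        raise RankDeficiencyError(
            f"{spec.name}: design matrix is rank deficient; "
            f"collinear columns: {bad}"
        )


# ---------------------------------------------------------------------------
# cluster-robust covariance


def _cluster_codes(design: Design, scheme: str) -> list[np.ndarray]:
    if scheme in ("year", "region", "year_region"):
        return [design.clusters[scheme]]
    if scheme == "twoway":
        return [
            design.clusters["year"],
            design.clusters["region"],
            design.clusters["year_region"],
        ]
    if scheme == "none":
        return []
    raise FitError(f"unknown clustering scheme {scheme!r}")


def clustered_cov(
    X: np.ndarray,
    resid: np.ndarray,
    codes: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """One-way cluster-robust sandwich covariance for a (W)LS fit.

    Uses the finite-sample correction G/(G-1) * (n-1)/(n-k), so with every
    observation its own cluster this reduces exactly to the HC1
    heteroscedasticity-robust covariance.
    """
    n, k = X.shape
    G = int(codes.max()) + 1
    if G < 2:
        raise ClusterError("clustered covariance requires >= 2 clusters")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    bread = np.linalg.inv(X.T @ (X * w[:, None]))
    scores = X * (w * resid)[:, None]
    S = np.zeros((G, k))
    np.add.at(S, codes, scores)
    meat = S.T @ S
    c = G / (G - 1) * (n - 1) / (n - k)
    return c * bread @ meat @ bread


def clustered_se(
    X: np.ndarray,
    resid: np.ndarray,
    codes: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster-robust standard errors (square root of the sandwich diagonal)."""
    return np.sqrt(np.diag(clustered_cov(X, resid, codes, weights)))


def _robust_cov(design: Design, resid: np.ndarray, scheme: str,
                weights: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Covariance and small-sample df for the configured scheme.

    Two-way clustering uses the inclusion-exclusion combination
    V(year) + V(region) - V(year x region); df follows the smallest
    cluster dimension.
    """
    X = design.matrix
    comps = _cluster_codes(design, scheme)
    if not comps:  # classical (homoscedastic) covariance
        n, k = X.shape
        w = np.ones(n) if weights is None else weights
        s2 = (w * resid**2).sum() / (n - k)
        return s2 * np.linalg.inv(X.T @ (X * w[:, None])), n - k
    if scheme == "twoway":
        Va = clustered_cov(X, resid, comps[0], weights)
        Vb = clustered_cov(X, resid, comps[1], weights)
        Vab = clustered_cov(X, resid, comps[2], weights)
        V = Va + Vb - Vab
        G = min(int(comps[0].max()) + 1, int(comps[1].max()) + 1)
        return V, G - 1
    codes = comps[0]
    return clustered_cov(X, resid, codes, weights), int(codes.max())


def _coef_table(
    params: np.ndarray, cov: np.ndarray, terms, df: int
) -> pd.DataFrame:
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, params / se, np.nan)
    p = 2 * stats.t.sf(np.abs(t), max(df, 1))
    return pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "t": t,
            "pvalue": p,
            "stars": [significance_stars(v) for v in p],
        },
        index=pd.Index(terms, name="term"),
    )


# ---------------------------------------------------------------------------
# estimation stages


def fit_ols(panel: Panel, spec: ModelSpec) -> JustPopeFit:
    """First-stage OLS fit of the mean equation with clustered inference."""
    design = build_design(panel, spec)
    res = sm.OLS(design.y, design.matrix).fit()
    resid = design.y - design.matrix @ res.params
    cov, df = _robust_cov(design, resid, spec.cluster)
    table = _coef_table(res.params, cov, design.X.columns, df)
    return JustPopeFit(
        name=spec.name,
        n_obs=design.n_obs,
        mean_yield=float(design.y.mean()),
        mean_ols=table,
        r2_ols=float(res.rsquared),
        ols_residuals=resid,
        design=design,
        spec=spec,
    )


def fit_variance(
    residuals: np.ndarray, design: Design, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Second stage: regress ln(residual^2) on the mean-equation covariates.

    Residual magnitudes below the configured quantile of the nonzero
    magnitudes are floored before logging (count returned) so near-exact
    fits cannot produce -inf responses.  Returns (coefficient table,
    fitted log-variance per observation, number floored).
    """
    absr = np.abs(np.asarray(residuals, float))
    if np.all(absr == 0):
        raise DegenerateVarianceError(
            "all mean-equation residuals are zero; variance equation undefined"
        )
    n_floored = 0
    if spec.resid_floor_quantile > 0:
        floor = np.quantile(absr[absr > 0], spec.resid_floor_quantile)
        n_floored = int((absr < floor).sum())
        absr = np.maximum(absr, floor)
    z = np.log(absr**2)
    res = sm.OLS(z, design.matrix).fit()
    zr = z - design.matrix @ res.params
    cov, df = _robust_cov(design, zr, spec.cluster)
    table = _coef_table(res.params, cov, design.X.columns, df)
    fitted = design.matrix @ res.params
    return table, fitted, n_floored


def fit_fgls(panel: Panel, spec: ModelSpec) -> JustPopeFit:
    """Full Just-Pope fit: OLS, variance equation, reweighted mean equation.

    One reweighting pass by default (``spec.fgls_iterations`` controls
    further iterations).  Weights are 1/exp(fitted log-variance),
    normalized to unit mean — WLS estimates are invariant to a positive
    rescaling of all weights.
    """
    fit = fit_ols(panel, spec)
    design = fit.design
    resid = fit.ols_residuals
    for _ in range(max(1, spec.fgls_iterations)):
        vtable, fitted_logvar, n_floored = fit_variance(resid, design, spec)
        w = np.exp(-fitted_logvar)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            bad = int(np.argmin(np.isfinite(w) & (w > 0)))
            raise FitError(
                f"{spec.name}: non-finite FGLS weight at row {bad} "
                f"(fitted log-variance {fitted_logvar[bad]:.3f}); "
                f"covariates: {design.X.iloc[bad].to_dict()}"
            )
        w = w / w.mean()
        res = sm.WLS(design.y, design.matrix, weights=w).fit()
        resid = design.y - design.matrix @ res.params

    cov, df = _robust_cov(design, resid, spec.cluster, weights=w)
    fit.mean_fgls = _coef_table(res.params, cov, design.X.columns, df)
    fit.variance = vtable
    fit.fitted_log_variance = fitted_logvar
    fit.n_floored = n_floored
    fit.r2_fgls = float(res.rsquared)
    fit.weights = w
    fit.weight_summary = {
        "min": float(w.min()),
        "max": float(w.max()),
        "ratio": float(w.max() / w.min()),
        "n_floored_residuals": n_floored,
    }
    return fit


# ---------------------------------------------------------------------------
# reporting


def fit_report(fits: dict[str, JustPopeFit]) -> pd.DataFrame:
    """Per-type summary: OLS yield / JP variance / JP yield vintage coefficients.

    Mirrors the published per-type results layout (coefficient columns with
    significance stars, observation count, mean yield).
    """
    rows = []
    for name, fit in fits.items():
        row = {
            "wheat_type": name,
            "ols_yield": fit.mean_ols.loc["lnrlyr", "estimate"],
            "ols_stars": fit.mean_ols.loc["lnrlyr", "stars"],
            "jp_variance": np.nan,
            "jp_variance_stars": "",
            "jp_yield": np.nan,
            "jp_yield_stars": "",
            "n_obs": fit.n_obs,
            "mean_yield_kg_ha": fit.mean_yield,
        }
        if fit.variance is not None:
            row["jp_variance"] = fit.variance.loc["lnrlyr", "estimate"]
            row["jp_variance_stars"] = fit.variance.loc["lnrlyr", "stars"]
        if fit.mean_fgls is not None:
            row["jp_yield"] = fit.mean_fgls.loc["lnrlyr", "estimate"]
            row["jp_yield_stars"] = fit.mean_fgls.loc["lnrlyr", "stars"]
        rows.append(row)
    return pd.DataFrame(rows)


def full_coefficients(fits: dict[str, JustPopeFit]) -> pd.DataFrame:
    """Long-format table of every coefficient of every equation of every fit."""
    parts = []
    for name, fit in fits.items():
        for eq, table in (
            ("ols_yield", fit.mean_ols),
            ("jp_variance", fit.variance),
            ("jp_yield", fit.mean_fgls),
        ):
            if table is None:
                continue
            t = table.reset_index()
            t.insert(0, "equation", eq)
            t.insert(0, "wheat_type", name)
            parts.append(t)
    return pd.concat(parts, ignore_index=True)
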