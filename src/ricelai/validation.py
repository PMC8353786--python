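"""Cross-validated model evaluation and the whole-pipeline report.

The evaluation protocol: samples (plot x date observations pooled over all
cultivars) are randomly split into k mutually exclusive folds (k = 10 by
default). Each fold serves once as validation for a model trained on the
other k-1; the reported coefficients and errors are the arithmetic means of
the per-fold values,

    Coef = mean_i(Coef_i),  RMSE = mean_i(RMSE_i),
    CV   = mean_i(RMSE_i / mean(measured LAI_i)),
    Bias = mean_i(mean_j(estimated LAI_j - measured LAI_j)).

Stage-stratified metrics re-score one whole-season fit separately on
pre-heading and post-heading samples, exposing the characteristic pattern of
VI-only models (over-estimation before heading, under-estimation after).
The hysteresis gap quantifies how far apart the two stages' LAI-vs-predictor
relations sit: separate lines are fit per stage and the mean absolute
difference of their predictions over the shared predictor range is
normalised by the mean measured LAI (0 = no hysteresis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import PlotObservation, observation_table
from .indices import (
    INDEX_NAMES,
    BandRoleMap,
    compute_all_indices,
    resolve_bands,
)
from .models import FitResult, ModelForm, fit_linear, predictor_value, r_squared

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVSummary:
    """Per-fold and averaged k-fold cross-validation results."""

    index: str
    form: ModelForm
    k: int
    seed: int
    n_samples: int
    slope_folds: tuple[float, ...]
    intercept_folds: tuple[float, ...]
    rmse_folds: tuple[float, ...]
    cv_folds: tuple[float, ...]
    bias_folds: tuple[float, ...]

    @property
    def slope(self) -> float:
        return float(np.mean(self.slope_folds))

    @property
    def intercept(self) -> float:
        return float(np.mean(self.intercept_folds))

    @property
    def rmse(self) -> float:
        return float(np.mean(self.rmse_folds))

    @property
    def cv(self) -> float:
        """Coefficient of variation of the error, as a fraction."""
        return float(np.mean(self.cv_folds))

    @property
    def bias(self) -> float:
        return float(np.mean(self.bias_folds))


@dataclass(frozen=True)
class StageMetrics:
    """Whole-season model re-scored on one phenology stage."""

    stage: str
    n: int
    rmse: float
    cv: float
    bias: float


def add_vi_columns(
    table: pd.DataFrame,
    bands: BandRoleMap | None = None,
    osavi_variant: str = "red_edge",
) -> pd.DataFrame:
    """Attach the eight index columns to an observation table."""
    if bands is None:
        bands = resolve_bands()
    wl_cols = [f"r{w}" for w in bands.wavelengths]
    refl = table[wl_cols].to_numpy(dtype=float)
    out = table.copy()
    values = {name: np.full(len(table), np.nan) for name in INDEX_NAMES}
    for i, row in enumerate(refl):
        if not np.all(np.isfinite(row)):
            continue
        for name, v in compute_all_indices(row, bands, osavi_variant).items():
            values[name][i] = v
    for name in INDEX_NAMES:
        out[name] = values[name]
    return out


def prepare_xy(
    table: pd.DataFrame, index: str, form: ModelForm
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Predictor/response arrays after dropping invalid or undefined samples."""
    df = table[table["valid"]].copy() if "valid" in table else table.copy()
    df = df[np.isfinite(df[index]) & np.isfinite(df["lai"])
            & np.isfinite(df["height"])]
    if form is ModelForm.H_TIMES_LNVI:
        n_domain = int((df[index] <= -1).sum())
        if n_domain:
            logger.info("excluding %d samples with %s <= -1 under ln form",
                        n_domain, index)
            df = df[df[index] > -1]
    x = predictor_value(df[index].to_numpy(), df["height"].to_numpy(), form)
    y = df["lai"].to_numpy(dtype=float)
    return np.asarray(x, dtype=float), y, df


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous chunks; remainder spread over the
    leading folds. Every sample lands in exactly one fold."""
    if not 2 <= k <= n:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


def kfold_cv(
    observations: Sequence[PlotObservation] | pd.DataFrame,
    index: str,
    form: ModelForm,
    k: int = 10,
    seed: int = 0,
    bands: BandRoleMap | None = None,
    cv_denominator: str = "fold",
) -> CVSummary:
    """k-fold cross-validation of one (index, model form) combination.

    ``cv_denominator`` selects the mean measured LAI used in CV_i: the
    validation fold's own mean ("fold", default) or the global mean
    ("global").
    """
    table = _as_vi_table(observations, bands)
    x, y, _ = prepare_xy(table, index, form)
    folds = make_folds(len(x), k, seed)
    global_mean = float(y.mean())

    slopes, intercepts, rmses, cvs, biases = [], [], [], [], []
    for i, val_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(len(x)), val_idx)
        fit = fit_linear(x[train], y[train])
        pred = fit.predict(x[val_idx])
        err = pred - y[val_idx]
        rmse_i = float(np.sqrt(np.mean(err**2)))
        denom = float(y[val_idx].mean()) if cv_denominator == "fold" \
            else global_mean
        slopes.append(fit.slope)
        intercepts.append(fit.intercept)
        rmses.append(rmse_i)
        cvs.append(rmse_i / denom)
        biases.append(float(err.mean()))
    return CVSummary(
        index=index, form=form, k=k, seed=seed, n_samples=len(x),
        slope_folds=tuple(slopes), intercept_folds=tuple(intercepts),
        rmse_folds=tuple(rmses), cv_folds=tuple(cvs),
        bias_folds=tuple(biases),
    )


def stratified_metrics(
    observations: Sequence[PlotObservation] | pd.DataFrame,
    fit: FitResult,
    form: ModelForm,
    index: str,
    bands: BandRoleMap | None = None,
) -> dict[str, StageMetrics | None]:
    """Score one whole-season fit separately on each phenology stage."""
    table = _as_vi_table(observations, bands)
    x, y, df = prepare_xy(table, index, form)
    out: dict[str, StageMetrics | None] = {}
    stages = df["stage"].to_numpy()
    for stage in ("pre-heading", "post-heading"):
        sel = stages == stage
        if not sel.any():
            out[stage] = None
            continue
        err = fit.predict(x[sel]) - y[sel]
        rmse = float(np.sqrt(np.mean(err**2)))
        out[stage] = StageMetrics(
            stage=stage, n=int(sel.sum()), rmse=rmse,
            cv=rmse / float(y[sel].mean()), bias=float(err.mean()),
        )
    return out


def hysteresis_gap(
    observations: Sequence[PlotObservation] | pd.DataFrame,
    index: str,
    form: ModelForm = ModelForm.VI_ONLY,
    bands: BandRoleMap | None = None,
    n_grid: int = 101,
) -> float:
    """Mean absolute difference between the pre- and post-heading
    LAI-vs-predictor lines over the shared predictor range, normalised by
    the mean measured LAI. NaN when the stage ranges do not overlap or a
    stage is empty."""
    table = _as_vi_table(observations, bands)
    x, y, df = prepare_xy(table, index, form)
    stages = df["stage"].to_numpy()
    fits = {}
    ranges = {}
    for stage in ("pre-heading", "post-heading"):
        sel = stages == stage
        if sel.sum() < 2 or np.ptp(x[sel]) == 0:
            return math.nan
        fits[stage] = fit_linear(x[sel], y[sel])
        ranges[stage] = (float(x[sel].min()), float(x[sel].max()))
    lo = max(r[0] for r in ranges.values())
    hi = min(r[1] for r in ranges.values())
    if hi <= lo:
        return math.nan
    grid = np.linspace(lo, hi, n_grid)
    diff = np.abs(fits["pre-heading"].predict(grid)
                  - fits["post-heading"].predict(grid))
    return float(diff.mean() / y.mean())


def _as_vi_table(
    observations: Sequence[PlotObservation] | pd.DataFrame,
    bands: BandRoleMap | None,
) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        table = observations
        if not set(INDEX_NAMES).issubset(table.columns):
            table = add_vi_columns(table, bands)
        return table
    return add_vi_columns(observation_table(list(observations)), bands)


# ---------------------------------------------------------------------------
# whole-pipeline report


@dataclass
class ReportBundle:
    """All whole-season result tables of one pipeline run."""

    r2_whole_season: pd.DataFrame       # index x form R²
    cv_table: pd.DataFrame              # RMSE/CV per index x form (k-fold)
    stage_table: pd.DataFrame           # stage-stratified RMSE/CV/Bias
    final_equations: pd.DataFrame       # whole-season fitted coefficients
    hysteresis: pd.DataFrame            # gap per index x form
    valid_counts: pd.DataFrame          # valid plots per flight date
    settings: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = ["Whole-season LAI model report", "=" * 31, ""]
        lines.append("Settings: " + ", ".join(
            f"{k}={v}" for k, v in self.settings.items()))
        lines.append("")
        lines.append("Whole-season R² (index x model form):")
        lines.append(self.r2_whole_season.round(3).to_string())
        lines.append("")
        lines.append("10-fold CV error (RMSE in LAI units, CV in %):")
        lines.append(self.cv_table.round(3).to_string(index=False))
        lines.append("")
        lines.append("Stage-stratified metrics (whole-season fit):")
        lines.append(self.stage_table.round(3).to_string(index=False))
        lines.append("")
        lines.append("Fitted whole-season equations:")
        for r in self.final_equations.itertuples():
            lines.append(
                f"  LAI = {r.slope:.2f} x {r.predictor} + {r.intercept:.2f}"
                f"  (R² = {r.r2:.2f}, RMSE = {r.rmse:.2f})"
            )
        lines.append("")
        lines.append("Valid plots per flight date:")
        lines.append(self.valid_counts.to_string(index=False))
        return "\n".join(lines)


def analyze_observations(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    bands: BandRoleMap | None = None,
    osavi_variant: str = "red_edge",
    cv_denominator: str = "fold",
) -> ReportBundle:
    """Produce every result table from an observation table."""
    if bands is None:
        bands = resolve_bands()
    table = add_vi_columns(table, bands, osavi_variant) \
        if not set(INDEX_NAMES).issubset(table.columns) else table

    forms = list(ModelForm)
    r2_rows = {}
    cv_rows = []
    stage_rows = []
    hyst_rows = []
    eq_rows = []
    for index in INDEX_NAMES:
        r2_rows[index] = {}
        for form in forms:
            x, y, _ = prepare_xy(table, index, form)
            r2_rows[index][form.value] = r_squared(x, y)
            summary = kfold_cv(table, index, form, k=k, seed=seed,
                               bands=bands, cv_denominator=cv_denominator)
            cv_rows.append(dict(
                index=index, form=form.value, rmse=summary.rmse,
                cv_pct=100.0 * summary.cv, bias=summary.bias,
                slope=summary.slope, intercept=summary.intercept,
                n=summary.n_samples, k=k,
            ))
            whole = fit_linear(x, y)
            if form is ModelForm.H_TIMES_LNVI:
                eq_rows.append(dict(
                    index=index, predictor=f"H x ln({index}+1)",
                    slope=whole.slope, intercept=whole.intercept,
                    r2=whole.r2, rmse=whole.rmse, n=whole.n_samples,
                ))
            for stage, m in stratified_metrics(
                    table, whole, form, index, bands).items():
                if m is None:
                    continue
                stage_rows.append(dict(
                    index=index, form=form.value, stage=stage, n=m.n,
                    rmse=m.rmse, cv_pct=100.0 * m.cv, bias=m.bias,
                ))
            hyst_rows.append(dict(
                index=index, form=form.value,
                gap=hysteresis_gap(table, index, form, bands),
            ))

    valid_counts = (
        table.groupby("dat")["valid"].sum().astype(int).rename("n_valid")
        .reset_index()
    ) if "valid" in table else pd.DataFrame(columns=["dat", "n_valid"])

    return ReportBundle(
        r2_whole_season=pd.DataFrame(r2_rows).T,
        cv_table=pd.DataFrame(cv_rows),
        stage_table=pd.DataFrame(stage_rows),
        final_equations=pd.DataFrame(eq_rows),
        hysteresis=pd.DataFrame(hyst_rows),
        valid_counts=valid_counts,
        settings=dict(k=k, seed=seed, bands=bands.describe(),
                      osavi_variant=osavi_variant,
                      cv_denominator=cv_denominator),
    )


def run_full_analysis(config: Mapping) -> ReportBundle:
    """End-to-end pipeline from a configuration mapping.

    The config either describes a synthetic campaign
    (``{"synthetic": {"n_cultivars": .., "dats": [..], "seed": ..,
    "first_campaign_water": ..}}``) or points to an extracted observation
    table (``{"observations_csv": path}``). Analysis settings (k, seed,
    band roles, osavi_variant) sit at the top level.
    """
    from .extraction import extract_observations
    from .synthetic import generate_campaign

    bands = resolve_bands(config.get("band_roles"))
    k = int(config.get("k", 10))
    seed = int(config.get("seed", 0))
    osavi_variant = config.get("osavi_variant", "red_edge")

    if "synthetic" in config:
        from .synthetic import DEFAULT_CAMPAIGN_DATS

        syn = dict(config["synthetic"])
        campaign = generate_campaign(
            n_cultivars=int(syn.get("n_cultivars", 48)),
            dats=tuple(syn.get("dats", DEFAULT_CAMPAIGN_DATS)),
            seed=int(syn.get("seed", seed)),
            first_campaign_water=bool(syn.get("first_campaign_water", True)),
        )
        obs = []
        for scene in campaign.scenes:
            obs.extend(extract_observations(
                scene, campaign.true_calibration, campaign.cultivars,
                campaign.sampling,
            ))
        table = observation_table(obs)
    elif "observations_csv" in config:
        table = pd.read_csv(config["observations_csv"])
    else:
        from .exceptions import ConfigurationError
        raise ConfigurationError(
            "config must provide either 'synthetic' or 'observations_csv'"
        )
    return analyze_observations(
        table, k=k, seed=seed, bands=bands, osavi_variant=osavi_variant,
        cv_denominator=config.get("cv_denominator", "fold"),
    )
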