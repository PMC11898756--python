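"""Per-protein turnover kinetics from pulse-labeling quantification tables.

The model for each protein is a straight line through the log10-transformed
series versus time:

* log10(H/L ratio) vs time — its zero crossing, ``-intercept/slope``, is the
  replacement time: the moment newly synthesized (heavy) protein equals the
  pre-shift (light) pool.  The cohort median replacement time proxies the
  culture generation time.
* log10(relative light abundance) vs time — the negated slope is the
  disappearance rate; ``log10(2) / rate`` is the protein half-life.
* log10(relative heavy abundance) vs time — the slope is the production rate.

Quality gates: a model must explain at least 70% of the variation (R^2 >=
0.70) and rest on at least four observations.  Models failing the gate get
one chance at single-outlier removal: an observation whose absolute residual
exceeds the median absolute residual plus twice its MAD (normal-consistent,
constant 1.4826) is removed — the worst one only — and the model refit once.
Proteins whose half-life sits outside median +/- 2*MAD of the cohort
half-lives are classified as turning over faster or slower than dilution by
growth; the rest disappear passively with the growing cell mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

__all__ = [
    "LinearFit",
    "LabeledSeries",
    "TurnoverEstimate",
    "CohortSummary",
    "fit_log_linear",
    "remove_single_outliers",
    "replacement_time",
    "component_rate",
    "resolve_sparse_ratio",
    "classify_vs_growth",
    "run_turnover_pipeline",
]

R2_MIN_DEFAULT = 0.70
MIN_OBS_DEFAULT = 4
MAD_K_DEFAULT = 2.0

Classification = Literal[
    "dilution_by_growth", "faster_than_growth", "slower_than_growth", "unassessed"
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of log10(value) against time.

    ``slope`` is log10 units per hour, ``intercept`` the log10 value at t=0.
    ``removed_points`` records positional indices (into the fitted arrays)
    dropped as outliers.
    """

    slope: float
    intercept: float
    r_squared: float
    n_obs: int
    removed_points: tuple[int, ...] = ()
    passed_quality: bool = False

    @property
    def defined(self) -> bool:
        return math.isfinite(self.slope)


_NO_FIT = LinearFit(math.nan, math.nan, 0.0, 0)


@dataclass(frozen=True)
class LabeledSeries:
    """One protein's aligned light/heavy intensities and H/L ratios."""

    protein_id: str
    times: np.ndarray  # minutes post-shift
    light: np.ndarray
    heavy: np.ndarray
    hl_ratio: np.ndarray
    includes_t0: bool = True

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.light) == len(self.heavy) == len(self.hl_ratio) == n):
            raise ValueError("times/light/heavy/hl_ratio must be aligned")


@dataclass
class TurnoverEstimate:
    """Kinetic summary for one protein; absent quantities are ``None``."""

    protein_id: str
    replacement_time: float | None = None  # minutes
    disappearance_rate: float | None = None  # log10 / h, positive = declining
    production_rate: float | None = None  # log10 / h
    half_life: float | None = None  # minutes
    classification: Classification = "unassessed"
    n_hl_ratios: int = 0
    replacement_absence_reason: str | None = None


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level medians over quality-passing models.

    The median replacement time serves as the proxy for the culture
    generation time after the shift.
    """

    median_replacement_time: float | None
    replacement_mad: float | None
    half_life_median: float | None
    half_life_mad: float | None
    n_replacement_models: int
    n_disappearance_models: int
    n_production_models: int


def log10_rate_to_per_hour(rate_log10_per_h: float) -> float:
    """Convert a log10/h slope to a natural-log first-order rate in h^-1."""
    return rate_log10_per_h * math.log(10.0)


def _ols_log10(t_min: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS of log10(values) on time in hours.

    Returns (slope, intercept, r_squared); R^2 of a zero-variance response
    is defined as 0.
    """
    x = t_min / 60.0
    y = np.log10(values)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0.0 else 1.0 - float(((y - (intercept + slope * x)) ** 2).sum()) / syy
    return slope, intercept, max(0.0, min(1.0, r2))


def fit_log_linear(
    times: Sequence[float],
    values: Sequence[float],
    *,
    r2_min: float = R2_MIN_DEFAULT,
    min_obs: int = MIN_OBS_DEFAULT,
) -> LinearFit:
    """Fit log10(values) vs time (minutes); no observations are rejected here.

    Fewer than two finite points, or zero time variance, yield an undefined
    (no-fit) result.  Non-positive values are an error: the log-linear model
    is only meaningful for positive intensities/ratios.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if (v <= 0).any():
        raise ValueError("values must be strictly positive for a log-linear fit")
    if len(t) < 2 or np.ptp(t) == 0.0:
        return replace(_NO_FIT, n_obs=len(t))
    slope, intercept, r2 = _ols_log10(t, v)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_obs=len(t),
        passed_quality=(r2 >= r2_min and len(t) >= min_obs),
    )


def remove_single_outliers(
    fit: LinearFit,
    times: Sequence[float],
    values: Sequence[float],
    *,
    r2_min: float = R2_MIN_DEFAULT,
    min_obs: int = MIN_OBS_DEFAULT,
    mad_k: float = MAD_K_DEFAULT,
    max_outliers: int = 1,
) -> LinearFit:
    """Drop the single worst outlying observation and refit once.

    An observation qualifies when its absolute residual strictly exceeds
    ``median(|r|) + mad_k * MAD(|r|)``.  If nothing qualifies the original
    fit is returned unchanged.  If removal would leave fewer than ``min_obs``
    observations the model is discarded (``passed_quality=False``) with the
    removal recorded.  ``max_outliers`` controls how many removal+refit
    rounds may run (the default, one, mirrors "single outlier observations").
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if not fit.defined or len(t) != fit.n_obs:
        return fit
    removed: list[int] = list(fit.removed_points)
    active = np.ones(len(t), dtype=bool)
    current = fit
    for _ in range(max_outliers):
        resid = np.abs(
            np.log10(v[active]) - (current.intercept + current.slope * t[active] / 60.0)
        )
        threshold = float(np.median(resid)) + mad_k * float(
            median_abs_deviation(resid, scale="normal")
        )
        if not (resid > threshold).any():
            break
        worst_local = int(np.argmax(resid))
        worst = int(np.flatnonzero(active)[worst_local])
        active[worst] = False
        removed.append(worst)
        if active.sum() < min_obs:
            return replace(
                current,
                n_obs=int(active.sum()),
                removed_points=tuple(removed),
                passed_quality=False,
            )
        refit = fit_log_linear(t[active], v[active], r2_min=r2_min, min_obs=min_obs)
        current = replace(refit, removed_points=tuple(removed))
        if current.passed_quality:
            break
    return current


def _fit_with_rescue(
    times: np.ndarray,
    values: np.ndarray,
    *,
    r2_min: float,
    min_obs: int,
    mad_k: float,
    max_outliers: int,
) -> LinearFit:
    """Fit; if the quality gate fails, attempt outlier removal."""
    fit = fit_log_linear(times, values, r2_min=r2_min, min_obs=min_obs)
    if fit.defined and not fit.passed_quality and fit.n_obs >= 2 and max_outliers > 0:
        fit = remove_single_outliers(
            fit, times, values,
            r2_min=r2_min, min_obs=min_obs, mad_k=mad_k, max_outliers=max_outliers,
        )
    return fit


def replacement_time(fit: LinearFit) -> float | None:
    """Zero crossing of a quality-passing log10(H/L) fit, in minutes.

    ``None`` when the model failed quality or the slope is non-positive
    (the log-ratio never reaches 0: a production-stagnation candidate).
    Use :func:`replacement_absence_reason` to distinguish the two.
    """
    if not fit.passed_quality or fit.slope <= 0:
        return None
    return -fit.intercept / fit.slope * 60.0


def replacement_absence_reason(
    fit: LinearFit, min_obs: int = MIN_OBS_DEFAULT
) -> str | None:
    if not fit.defined or fit.n_obs < min_obs:
        return "insufficient_points"
    if not fit.passed_quality:
        return "quality_fail"
    if fit.slope <= 0:
        return "non_crossing"
    return None


def component_rate(
    series: LabeledSeries,
    component: Literal["light", "heavy"],
    sample_totals: Sequence[float],
    *,
    r2_min: float = R2_MIN_DEFAULT,
    min_obs: int = MIN_OBS_DEFAULT,
    mad_k: float = MAD_K_DEFAULT,
    max_outliers: int = 1,
) -> LinearFit:
    """Fit log10(relative abundance) of one label channel vs time.

    Intensities are divided by their per-sample totals (relative iBAQ,
    correcting for arbitrary per-sample scale) before the log-linear fit.
    For the light channel the negated slope is the disappearance rate.
    """
    values = series.light if component == "light" else series.heavy
    totals = np.asarray(sample_totals, dtype=float)
    if len(totals) != len(series.times):
        raise ValueError("sample_totals must align with the series")
    rel = values / totals
    keep = np.isfinite(rel) & (rel > 0)
    if keep.sum() < 2:
        return replace(_NO_FIT, n_obs=int(keep.sum()))
    return _fit_with_rescue(
        series.times[keep], rel[keep],
        r2_min=r2_min, min_obs=min_obs, mad_k=mad_k, max_outliers=max_outliers,
    )


def resolve_sparse_ratio(
    estimate: TurnoverEstimate,
    n_hl_ratios: int,
    median_light_abundance: float,
    median_heavy_abundance: float,
    *,
    min_ratios: int = MIN_OBS_DEFAULT,
) -> TurnoverEstimate:
    """Apply the sparse-ratio disambiguation rule.

    When a protein has fewer than ``min_ratios`` H/L ratios yet both the
    light-based disappearance and heavy-based production models passed, the
    rate belonging to the channel with the lower median relative abundance
    is discarded — with so few direct ratio observations, the weaker channel
    is the less trustworthy of the two.
    """
    if n_hl_ratios >= min_ratios:
        return estimate
    if estimate.disappearance_rate is None or estimate.production_rate is None:
        return estimate
    out = replace_estimate(estimate)
    if median_light_abundance <= median_heavy_abundance:
        out.disappearance_rate = None
        out.half_life = None
    else:
        out.production_rate = None
    return out


def replace_estimate(estimate: TurnoverEstimate) -> TurnoverEstimate:
    return TurnoverEstimate(**vars(estimate))


def classify_vs_growth(
    estimates: Sequence[TurnoverEstimate],
    *,
    mad_k: float = MAD_K_DEFAULT,
) -> tuple[list[TurnoverEstimate], CohortSummary]:
    """Label each protein relative to dilution by growth.

    Half-lives outside ``median +/- mad_k * MAD`` of the cohort's half-life
    distribution mark proteins turning over faster (active degradation) or
    slower than the growing cell mass dilutes them.  Fewer than three
    half-lives leave everything unassessed.
    """
    out = [replace_estimate(e) for e in estimates]
    half_lives = np.array(
        [e.half_life for e in out if e.half_life is not None], dtype=float
    )
    if len(half_lives) >= 3:
        med = float(np.median(half_lives))
        mad = float(median_abs_deviation(half_lives, scale="normal"))
        for e in out:
            if e.half_life is None:
                e.classification = "unassessed"
            elif e.half_life < med - mad_k * mad:
                e.classification = "faster_than_growth"
            elif e.half_life > med + mad_k * mad:
                e.classification = "slower_than_growth"
            else:
                e.classification = "dilution_by_growth"
        hl_med, hl_mad = med, mad
    else:
        for e in out:
            e.classification = "unassessed"
        hl_med = hl_mad = None

    rep = np.array(
        [e.replacement_time for e in out if e.replacement_time is not None], float
    )
    summary = CohortSummary(
        median_replacement_time=float(np.median(rep)) if len(rep) else None,
        replacement_mad=(
            float(median_abs_deviation(rep, scale="normal")) if len(rep) else None
        ),
        half_life_median=hl_med,
        half_life_mad=hl_mad,
        n_replacement_models=int(len(rep)),
        n_disappearance_models=sum(e.disappearance_rate is not None for e in out),
        n_production_models=sum(e.production_rate is not None for e in out),
    )
    return out, summary


_REQUIRED_COLUMNS = (
    "protein_id", "sample", "time_min", "intensity_L", "intensity_H", "ratio_HL",
)


def _series_from_table(table: pd.DataFrame) -> tuple[list[LabeledSeries], np.ndarray]:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"quantification table lacks columns: {missing}")
    samples = (
        table[["sample", "time_min"]]
        .drop_duplicates()
        .sort_values(["time_min", "sample"])
        .reset_index(drop=True)
    )
    order = pd.MultiIndex.from_frame(samples)
    wide_l = table.pivot_table(
        index="protein_id", columns=["sample", "time_min"],
        values="intensity_L", aggfunc="first", dropna=False,
    ).reindex(columns=order)
    wide_h = table.pivot_table(
        index="protein_id", columns=["sample", "time_min"],
        values="intensity_H", aggfunc="first", dropna=False,
    ).reindex(columns=order)
    wide_r = table.pivot_table(
        index="protein_id", columns=["sample", "time_min"],
        values="ratio_HL", aggfunc="first", dropna=False,
    ).reindex(columns=order)
    times = samples["time_min"].to_numpy(dtype=float)
    totals = np.nansum(wide_l.to_numpy(), axis=0) + np.nansum(wide_h.to_numpy(), axis=0)
    series = [
        LabeledSeries(
            protein_id=str(pid),
            times=times,
            light=wide_l.loc[pid].to_numpy(dtype=float),
            heavy=wide_h.loc[pid].to_numpy(dtype=float),
            hl_ratio=wide_r.loc[pid].to_numpy(dtype=float),
            includes_t0=bool((times == 0).any()),
        )
        for pid in sorted(wide_l.index)
    ]
    return series, totals


def run_turnover_pipeline(
    table: pd.DataFrame,
    *,
    r2_min: float = R2_MIN_DEFAULT,
    min_obs: int = MIN_OBS_DEFAULT,
    mad_k: float = MAD_K_DEFAULT,
    max_outliers: int = 1,
) -> tuple[pd.DataFrame, CohortSummary]:
    """Full per-protein turnover analysis of a labeling quantification table.

    Steps, per protein: fit log10(H/L) vs time excluding t0 (no heavy label
    there) with outlier rescue; require R^2 >= ``r2_min``, >= ``min_obs``
    ratio observations, and >= ``min_obs`` light and heavy observations for a
    replacement time; fit relative-abundance models per label channel
    (including t0) for the disappearance and production rates; apply the
    sparse-ratio rule; derive half-lives from disappearance rates and
    classify against the cohort.  Deterministic; the output is sorted by
    protein id, so input row order is irrelevant.

    Returns ``(estimates, cohort)`` where ``estimates`` has one row per
    protein.
    """
    if table.empty:
        raise ValueError("quantification table is empty")
    series, totals = _series_from_table(table)
    estimates: list[TurnoverEstimate] = []
    for s in series:
        post = s.times > 0
        ratios = s.hl_ratio.copy()
        ratios[~post] = np.nan
        usable = np.isfinite(ratios) & (ratios > 0)
        n_ratios = int(usable.sum())
        est = TurnoverEstimate(protein_id=s.protein_id, n_hl_ratios=n_ratios)

        ratio_fit = _fit_with_rescue(
            s.times[usable], ratios[usable],
            r2_min=r2_min, min_obs=min_obs, mad_k=mad_k, max_outliers=max_outliers,
        ) if n_ratios >= 2 else replace(_NO_FIT, n_obs=n_ratios)

        n_light = int(np.isfinite(s.light).sum())
        n_heavy = int(np.isfinite(s.heavy[post]).sum())
        if ratio_fit.passed_quality and (n_light < min_obs or n_heavy < min_obs):
            # replacement models need >= min_obs light AND heavy observations
            est.replacement_absence_reason = "sparse_components"
        else:
            est.replacement_time = replacement_time(ratio_fit)
            est.replacement_absence_reason = replacement_absence_reason(
                ratio_fit, min_obs
            )

        light_fit = component_rate(
            s, "light", totals,
            r2_min=r2_min, min_obs=min_obs, mad_k=mad_k, max_outliers=max_outliers,
        )
        if light_fit.passed_quality:
            est.disappearance_rate = -light_fit.slope
        heavy_fit = component_rate(
            s, "heavy", totals,
            r2_min=r2_min, min_obs=min_obs, mad_k=mad_k, max_outliers=max_outliers,
        )
        if heavy_fit.passed_quality:
            est.production_rate = heavy_fit.slope

        rel_l = s.light / totals
        rel_h = s.heavy / totals
        est = resolve_sparse_ratio(
            est,
            n_ratios,
            float(np.nanmedian(rel_l)) if np.isfinite(rel_l).any() else 0.0,
            float(np.nanmedian(rel_h)) if np.isfinite(rel_h).any() else 0.0,
            min_ratios=min_obs,
        )
        if est.disappearance_rate is not None and est.disappearance_rate > 0:
            est.half_life = math.log10(2.0) / est.disappearance_rate * 60.0
        else:
            est.half_life = None
        estimates.append(est)

    estimates, summary = classify_vs_growth(estimates, mad_k=mad_k)
    frame = pd.DataFrame(
        {
            "protein_id": [e.protein_id for e in estimates],
            "replacement_time_min": [e.replacement_time for e in estimates],
            "disappearance_rate_log10_per_h": [e.disappearance_rate for e in estimates],
            "production_rate_log10_per_h": [e.production_rate for e in estimates],
            "half_life_min": [e.half_life for e in estimates],
            "classification": [e.classification for e in estimates],
            "n_hl_ratios": [e.n_hl_ratios for e in estimates],
            "replacement_absence_reason": [
                e.replacement_absence_reason for e in estimates
            ],
        }
    )
    return frame, summary
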