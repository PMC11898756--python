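"""Growth-rate estimation and fermentation-profile arithmetic.

Maximal specific growth rates come from the slope of ln(OD600) over the
most linear stretch of the curve: every contiguous window of at least
``min_window`` points is scanned, and among windows reaching R^2 >=
``r2_min`` the one with the highest R^2 (longest on ties) supplies the
slope.  Selecting by linearity rather than by steepest slope matters under
measurement noise: the steepest qualifying window is systematically the one
whose noise fluctuates upward, biasing the rate high, whereas the most
linear window is the exponential stretch itself.  Fermentation mode is
summarized
by the acetate share of the two measured organic acids (lactate + acetate),
rescaled to [0, 1]; arginine-deiminase pathway activity is proxied by
extracellular ornithine normalized to cell density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthRateFit",
    "FermentationProfile",
    "max_growth_rate",
    "fermentation_fractions",
    "condition_compare",
]


@dataclass(frozen=True)
class GrowthRateFit:
    """Windowed log-linear growth-rate estimate.

    ``mu`` is the natural-log slope in h^-1; ``window`` holds the (start,
    end) indices (inclusive) of the chosen stretch; ``meets_r2`` is False
    when no window reached the R^2 threshold and the best-R^2 window was
    used instead (a warning is issued).
    """

    mu: float
    window: tuple[int, int]
    r_squared: float
    meets_r2: bool


def max_growth_rate(
    time_min: Sequence[float],
    od600: Sequence[float],
    *,
    min_window: int = 4,
    r2_min: float = 0.99,
) -> GrowthRateFit:
    """Maximal specific growth rate (h^-1) from an OD600 time series.

    Scans all contiguous windows of >= ``min_window`` points, regresses
    ln(OD) on time in hours, and returns the slope of the most linear
    qualifying window: among windows with R^2 >= ``r2_min``, highest R^2
    wins, with longer windows preferred on ties.  If no window qualifies
    (noisy or flat curves) the best-R^2 window's slope is returned with a
    warning.  Invariant to rescaling the OD values.
    """
    t = np.asarray(time_min, dtype=float) / 60.0
    od = np.asarray(od600, dtype=float)
    if len(t) < min_window:
        raise ValueError(f"need at least {min_window} points, got {len(t)}")
    if (od <= 0).any():
        raise ValueError("od600 values must be positive")
    y = np.log(od)

    best_qualifying: GrowthRateFit | None = None
    best_overall: GrowthRateFit | None = None
    n = len(t)
    for i in range(0, n - min_window + 1):
        for j in range(i + min_window - 1, n):
            xs, ys = t[i : j + 1], y[i : j + 1]
            res = stats.linregress(xs, ys)
            r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 0.0
            fit = GrowthRateFit(float(res.slope), (i, j), float(r2), r2 >= r2_min)
            if best_overall is None or r2 > best_overall.r_squared:
                best_overall = fit
            if r2 >= r2_min and (
                best_qualifying is None
                or (fit.r_squared, j - i) > (
                    best_qualifying.r_squared,
                    best_qualifying.window[1] - best_qualifying.window[0],
                )
            ):
                best_qualifying = fit
    if best_qualifying is not None:
        return best_qualifying
    warnings.warn(
        f"no window of >= {min_window} points reached R^2 >= {r2_min}; "
        f"returning the best-R^2 window (R^2 = {best_overall.r_squared:.3f})",
        stacklevel=2,
    )
    return best_overall


@dataclass(frozen=True)
class FermentationProfile:
    """Organic-acid split and ADI-pathway proxy for one replicate."""

    condition: str
    replicate: int | None
    lactic_fraction: float | None
    acetic_fraction: float | None
    ornithine_per_od: float | None


def fermentation_fractions(
    table: pd.DataFrame,
    *,
    normalize: bool = False,
    peak_columns: Sequence[str] | None = None,
) -> list[FermentationProfile]:
    """Per-replicate fermentation profile from an NMR peak table.

    ``table`` needs ``lactate`` and ``acetate`` columns (total-normalized
    relative intensities), optionally ``ornithine`` and ``od600`` for the
    ADI proxy, plus ``condition``/``replicate`` labels.  With
    ``normalize=True`` the ``peak_columns`` (default: all metabolite
    columns present) are first divided by their row sum, for tables of raw
    peak intensities.  The acid fractions are scale-invariant either way;
    rows with no measurable acid signal get absent fractions.
    """
    for col in ("lactate", "acetate"):
        if col not in table.columns:
            raise ValueError(f"peak table lacks required column {col!r}")
    work = table.copy()
    if normalize:
        cols = list(peak_columns) if peak_columns is not None else [
            c
            for c in work.columns
            if c not in ("condition", "replicate", "od600")
        ]
        totals = work[cols].sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("cannot total-normalize rows with no signal")
        work[cols] = work[cols].div(totals, axis=0)

    profiles = []
    for _, row in work.iterrows():
        acid_total = row["lactate"] + row["acetate"]
        if acid_total > 0:
            acetic = float(row["acetate"] / acid_total)
            lactic = 1.0 - acetic
        else:
            acetic = lactic = None
        orn = None
        if "ornithine" in work.columns and "od600" in work.columns:
            if np.isfinite(row["ornithine"]) and row["od600"] > 0:
                orn = float(row["ornithine"] / row["od600"])
        profiles.append(
            FermentationProfile(
                condition=str(row.get("condition", "")),
                replicate=int(row["replicate"]) if "replicate" in work.columns else None,
                lactic_fraction=lactic,
                acetic_fraction=acetic,
                ornithine_per_od=orn,
            )
        )
    return profiles


def condition_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch test (unequal variances, Satterthwaite df).

    Returns ``(t, p)``.  Two zero-variance groups with equal means compare
    as identical: ``(0.0, 1.0)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math_inf_signed(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def math_inf_signed(delta: float) -> float:
    return float(np.inf) if delta > 0 else float(-np.inf)
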