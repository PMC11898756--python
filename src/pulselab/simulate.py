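"""Synthetic pulse-labeling, growth-curve and NMR peak-table generators.

The labeling generator emulates a dynamic SILAC experiment: a culture growing
on light lysine is shifted at t=0 into heavy-lysine medium, so pre-existing
protein stays light and newly made protein is heavy.  Per cell, with specific
growth rate ``mu`` (h^-1) and optional first-order active degradation
``k_deg``:

* light protein of a given species decays as ``a0 * exp(-(mu + k_deg) t)``
  (dilution by growth plus degradation; no new light synthesis), and
* heavy protein relaxes toward its post-shift target ``a1`` as
  ``a1 * (1 - exp(-(mu + k_deg) t))``, with synthesis optionally stopping
  entirely after ``stagnation_time``.

Intensities are reported the way a label-based MS experiment reports them:
within-sample relative abundances (every per-cell amount divided by the
per-sample total over all light and heavy species) scaled by an arbitrary
per-sample factor, with multiplicative log-normal measurement noise and a
detection-limit floor below which values are missing.  With ``a1 == a0`` and
``k_deg == 0`` the noise-free heavy/light ratio is exactly
``(a1/a0) * (exp(mu t) - 1)``, crossing 1 at the culture doubling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ProteinTruth",
    "GrowthSimSpec",
    "NmrSimSpec",
    "make_cohort",
    "simulate_labeling_experiment",
    "simulate_growth_curve",
    "simulate_nmr_tables",
]

#: arbitrary full-scale intensity so tables look like MS output
_INTENSITY_SCALE = 1e10


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one pulse-labeling shift experiment.

    Times are minutes post-shift; rates are per hour.  ``detection_limit``
    is a relative-abundance floor (fraction of the per-sample total signal)
    below which a measurement is reported missing, mimicking the instrument's
    dynamic range.  ``sample_scale_cv`` adds an arbitrary per-sample scale
    (harvesting/injection variation) that downstream relative-iBAQ
    normalization is meant to remove.
    """

    n_proteins: int
    mu_post: float
    sampling_times: tuple[float, ...]
    mu_pre: float | None = None
    n_t0_replicates: int = 2
    noise_cv: float = 0.2
    detection_limit: float = 1e-4
    sample_scale_cv: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        _require_finite("mu_post", self.mu_post)
        if self.mu_post <= 0:
            raise ValueError("mu_post must be > 0")
        times = tuple(float(t) for t in self.sampling_times)
        if not times:
            raise ValueError("sampling_times must be non-empty")
        _require_finite("sampling_times", *times)
        if any(t <= 0 for t in times):
            raise ValueError("sampling_times must be > 0 (t0 is added separately)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling_times must be strictly increasing")
        object.__setattr__(self, "sampling_times", times)
        if self.n_t0_replicates < 0:
            raise ValueError("n_t0_replicates must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.sample_scale_cv < 0:
            raise ValueError("sample_scale_cv must be >= 0")


@dataclass(frozen=True)
class ProteinTruth:
    """Ground-truth kinetic parameters for one protein.

    ``a0``/``a1`` are pre-/post-shift per-cell steady abundances in arbitrary
    units (``a1/a0`` is the expression fold change across the shift),
    ``k_deg`` an active first-order degradation rate in h^-1 on top of
    dilution, and ``stagnation_time`` the minute after the shift at which
    synthesis stops entirely (``inf`` = never, 0 = instantly).
    """

    protein_id: str
    a0: float
    a1: float
    k_deg: float = 0.0
    stagnation_time: float = math.inf

    def __post_init__(self) -> None:
        _require_finite("a0", self.a0)
        _require_finite("a1", self.a1)
        _require_finite("k_deg", self.k_deg)
        if self.a0 <= 0:
            raise ValueError("a0 must be > 0")
        if self.a1 < 0:
            raise ValueError("a1 must be >= 0")
        if self.k_deg < 0:
            raise ValueError("k_deg must be >= 0")
        if self.stagnation_time < 0:
            raise ValueError("stagnation_time must be >= 0")


def make_cohort(
    n: int,
    *,
    a1_over_a0: float = 1.0,
    k_deg: float = 0.0,
    stagnation_time: float = math.inf,
    abundance_sigma: float = 0.5,
    rng: np.random.Generator | None = None,
    prefix: str = "P",
) -> list[ProteinTruth]:
    """Build ``n`` proteins sharing one kinetic regime.

    Per-cell abundances ``a0`` are drawn log-normally with ``abundance_sigma``
    log10 standard deviation around 1, giving the ~1.5 orders-of-magnitude
    spread of a typical quantified bacterial proteome; ``a1 = a1_over_a0 *
    a0``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    a0 = 10.0 ** rng.normal(0.0, abundance_sigma, size=n)
    return [
        ProteinTruth(
            protein_id=f"{prefix}{i:05d}",
            a0=float(a0[i]),
            a1=float(a1_over_a0 * a0[i]),
            k_deg=k_deg,
            stagnation_time=stagnation_time,
        )
        for i in range(n)
    ]


def _per_cell_amounts(
    truths: Sequence[ProteinTruth], mu: float, t_hours: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-cell light and heavy amounts at one time point."""
    a0 = np.array([p.a0 for p in truths])
    a1 = np.array([p.a1 for p in truths])
    k = mu + np.array([p.k_deg for p in truths])
    t_stop = np.array([p.stagnation_time for p in truths]) / 60.0
    light = a0 * np.exp(-k * t_hours)
    grown = np.minimum(t_hours, t_stop)
    heavy = a1 * (1.0 - np.exp(-k * grown))
    # after synthesis stops, existing heavy protein dilutes/degrades too
    heavy = heavy * np.exp(-k * np.maximum(t_hours - t_stop, 0.0))
    return light, heavy


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_labeling_experiment(
    config: SimulationConfig, truths: Sequence[ProteinTruth]
) -> pd.DataFrame:
    """Generate a long-format light/heavy quantification table.

    Returns one row per protein and sample with columns ``protein_id``,
    ``sample``, ``time_min``, ``intensity_L``, ``intensity_H``, ``ratio_HL``.
    t0 is harvested in ``n_t0_replicates`` replicates with no heavy signal.
    Missing values (below the detection limit, or heavy at t0) are NaN.
    The heavy/light ratio is formed from the noisy intensities, as a search
    engine would report it.
    """
    if len(truths) == 0:
        raise ValueError("truths must be non-empty")
    if len(truths) != config.n_proteins:
        raise ValueError(
            f"config.n_proteins={config.n_proteins} but {len(truths)} truths given"
        )
    rng = np.random.default_rng(config.seed)
    samples: list[tuple[str, float]] = [
        (f"t0_r{i + 1}", 0.0) for i in range(config.n_t0_replicates)
    ]
    samples += [(f"t{int(t):03d}min", float(t)) for t in config.sampling_times]

    ids = [p.protein_id for p in truths]
    frames = []
    for sample_name, t_min in samples:
        light, heavy = _per_cell_amounts(truths, config.mu_post, t_min / 60.0)
        total = float(light.sum() + heavy.sum())
        rel_l = light / total
        rel_h = heavy / total
        scale = _INTENSITY_SCALE * float(_lognormal_factors(rng, config.sample_scale_cv, ()))
        obs_l = rel_l * _lognormal_factors(rng, config.noise_cv, len(truths)) * scale
        obs_h = rel_h * _lognormal_factors(rng, config.noise_cv, len(truths)) * scale
        obs_l[(obs_l <= 0) | (obs_l / scale < config.detection_limit)] = np.nan
        obs_h[(obs_h <= 0) | (obs_h / scale < config.detection_limit)] = np.nan
        if t_min == 0.0:
            obs_h[:] = np.nan  # no heavy label yet
        ratio = obs_h / obs_l
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": ids,
                    "sample": sample_name,
                    "time_min": t_min,
                    "intensity_L": obs_l,
                    "intensity_H": obs_h,
                    "ratio_HL": ratio,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class GrowthSimSpec:
    """Batch growth curve: flat lag, exponential phase at ``mu``, plateau."""

    mu: float
    od_start: float
    od_plateau: float
    lag_minutes: float = 0.0
    sample_interval_minutes: float = 30.0
    duration_minutes: float | None = None
    noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _require_finite("mu", self.mu)
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (self.od_plateau > self.od_start > 0):
            raise ValueError("need od_plateau > od_start > 0")
        if self.lag_minutes < 0 or self.sample_interval_minutes <= 0:
            raise ValueError("invalid lag or sampling interval")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def default_duration(self) -> float:
        if self.mu == 0:
            return self.lag_minutes + 480.0
        exp_span = math.log(self.od_plateau / self.od_start) / self.mu * 60.0
        return self.lag_minutes + exp_span + 120.0


def simulate_growth_curve(spec: GrowthSimSpec) -> pd.DataFrame:
    """OD600 time series with columns ``time_min`` and ``od600``."""
    rng = np.random.default_rng(spec.seed)
    duration = spec.duration_minutes or spec.default_duration()
    t = np.arange(0.0, duration + 1e-9, spec.sample_interval_minutes)
    grown = np.maximum(t - spec.lag_minutes, 0.0) / 60.0
    od = np.minimum(spec.od_start * np.exp(spec.mu * grown), spec.od_plateau)
    od = od * _lognormal_factors(rng, spec.noise_cv, len(t))
    return pd.DataFrame({"time_min": t, "od600": od})


@dataclass(frozen=True)
class NmrSimSpec:
    """Relative NMR peak intensities per growth condition.

    ``intensities`` maps each condition label to metabolite -> true
    total-normalized intensity; each mapping must sum to 1 (include an
    ``other`` bucket for the remaining peaks).  ``od600`` gives the harvest
    cell density per condition.
    """

    intensities: Mapping[str, Mapping[str, float]]
    od600: Mapping[str, float]
    n_replicates: int = 3
    noise_cv: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError("intensities must be non-empty")
        for label, peaks in self.intensities.items():
            vals = np.array(list(peaks.values()), float)
            if (vals < 0).any():
                raise ValueError(f"negative intensity in condition {label!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"intensities for condition {label!r} must sum to 1"
                )
            if label not in self.od600:
                raise ValueError(f"no od600 for condition {label!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_nmr_tables(spec: NmrSimSpec) -> pd.DataFrame:
    """Per-replicate peak table: condition, replicate, od600, one column per
    metabolite (noisy total-normalized relative intensities)."""
    rng = np.random.default_rng(spec.seed)
    metabolites = sorted({m for peaks in spec.intensities.values() for m in peaks})
    rows = []
    for label, peaks in spec.intensities.items():
        truth = np.array([peaks.get(m, 0.0) for m in metabolites])
        for rep in range(1, spec.n_replicates + 1):
            noisy = truth * _lognormal_factors(rng, spec.noise_cv, len(truth))
            od = spec.od600[label] * float(_lognormal_factors(rng, spec.noise_cv, ()))
            rows.append(
                {"condition": label, "replicate": rep, "od600": od}
                | dict(zip(metabolites, noisy))
            )
    return pd.DataFrame(rows)
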