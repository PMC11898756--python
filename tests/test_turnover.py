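"""Turnover kinetics: fitting oracles, quality gates, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pulselab as pl
from pulselab.turnover import (
    LabeledSeries,
    replacement_absence_reason,
    resolve_sparse_ratio,
)

LOG10E = math.log10(math.e)


def ols_oracle(times_min, values):
    """Independent normal-equations solution for log10(v) ~ hours."""
    x = np.asarray(times_min, float) / 60.0
    y = np.log10(np.asarray(values, float))
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - ss_res / ss_tot


class TestFitLogLinear:
    def test_exact_line_recovered(self):
        t = np.array([0, 15, 30, 45, 60, 120.0])
        v = 10 ** (0.5 + 0.002 * t)
        fit = pl.fit_log_linear(t, v)
        assert fit.slope == pytest.approx(0.12)  # 0.002/min = 0.12/h
        assert fit.intercept == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.passed_quality

    def test_constant_values_define_r2_zero(self):
        fit = pl.fit_log_linear([0, 30, 60, 90], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0
        assert not fit.passed_quality

    def test_agreement_with_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(3, 12)
            t = np.sort(rng.uniform(0, 240, n))
            v = 10 ** (rng.normal(0, 1) + rng.normal(0, 0.01) * t + rng.normal(0, 0.2, n))
            fit = pl.fit_log_linear(t, v)
            slope, intercept, r2 = ols_oracle(t, v)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)
            # second, independent route
            res = stats.linregress(t / 60.0, np.log10(v))
            assert fit.slope == pytest.approx(res.slope, abs=1e-10)

    def test_degenerate_inputs_yield_no_fit(self):
        assert not pl.fit_log_linear([10.0], [2.0]).defined
        assert not pl.fit_log_linear([30.0, 30.0], [1.0, 2.0]).defined

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError):
            pl.fit_log_linear([0, 10, 20], [1.0, -2.0, 3.0])


class TestOutlierRemoval:
    def test_gross_outlier_removed_and_refit_is_clean(self):
        t = np.arange(0, 120, 15.0)  # 8 points
        v = 10 ** (1.0 + 0.003 * t)
        v[3] *= 10 ** 2.0  # displace far beyond the spread
        fit = pl.fit_log_linear(t, v)
        assert not fit.passed_quality
        # independent threshold check: median |r| + 2 * 1.4826 * MAD
        slope, intercept, _ = ols_oracle(t, v)
        resid = np.abs(np.log10(v) - (intercept + slope * t / 60))
        mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        assert resid[3] > np.median(resid) + 2 * mad
        refit = pl.remove_single_outliers(fit, t, v)
        assert refit.removed_points == (3,)
        assert refit.r_squared == pytest.approx(1.0)
        assert refit.passed_quality

    def test_equal_residual_magnitudes_remove_nothing(self):
        t = np.array([0, 10, 20, 30, 40, 50, 60, 70.0])
        signs = np.array([1, -1, -1, 1, 1, -1, -1, 1.0])  # balanced pattern
        v = 10 ** (0.2 + 0.004 * t + 0.05 * signs)
        fit = pl.fit_log_linear(t, v)
        resid = np.log10(v) - (fit.intercept + fit.slope * t / 60)
        assert np.allclose(np.abs(resid), np.abs(resid[0]))  # construction holds
        refit = pl.remove_single_outliers(fit, t, v)
        assert refit == fit

    def test_removal_below_min_obs_discards_model(self):
        """A removal that leaves fewer observations than the gate requires
        discards the model instead of reporting a thin refit."""
        t = np.array([0, 20, 40, 60, 80.0])
        v = 10 ** (0.1 + 0.005 * t)
        v[2] *= 10 ** 1.5
        fit = pl.fit_log_linear(t, v, min_obs=5)
        refit = pl.remove_single_outliers(fit, t, v, min_obs=5)
        assert refit.removed_points == (2,)
        assert refit.n_obs == 4
        assert not refit.passed_quality


class TestReplacementTime:
    def test_zero_intercept_crosses_at_zero(self):
        fit = pl.LinearFit(slope=0.5, intercept=0.0, r_squared=1.0, n_obs=8,
                           passed_quality=True)
        assert pl.replacement_time(fit) == pytest.approx(0.0)

    def test_known_crossing(self):
        fit = pl.LinearFit(slope=0.5, intercept=-1.0, r_squared=1.0, n_obs=8,
                           passed_quality=True)
        assert pl.replacement_time(fit) == pytest.approx(120.0)  # 2 h

    def test_negative_slope_is_non_crossing_not_quality_failure(self):
        fit = pl.LinearFit(slope=-0.2, intercept=-1.0, r_squared=0.95, n_obs=8,
                           passed_quality=True)
        assert pl.replacement_time(fit) is None
        assert replacement_absence_reason(fit) == "non_crossing"
        bad = pl.LinearFit(slope=0.5, intercept=-1.0, r_squared=0.4, n_obs=8,
                           passed_quality=False)
        assert replacement_absence_reason(bad) == "quality_fail"

    def test_noiseless_series_crossing_near_doubling_time(self):
        """log10(exp(mu t) - 1) sampled at the 8-point design: the fitted
        crossing sits within 3 min of the 96-min doubling time."""
        mu = math.log(2) / 96.0  # per minute
        t = np.arange(15.0, 121.0, 15.0)
        ratios = np.exp(mu * t) - 1.0
        fit = pl.fit_log_linear(t, ratios)
        assert abs(pl.replacement_time(fit) - 96.0) < 3.0


class TestComponentRate:
    def _series(self, times, light, heavy=None):
        n = len(times)
        heavy = heavy if heavy is not None else np.full(n, np.nan)
        return LabeledSeries(
            protein_id="P", times=np.asarray(times, float),
            light=np.asarray(light, float), heavy=np.asarray(heavy, float),
            hl_ratio=np.full(n, np.nan),
        )

    def test_exponential_light_decay_rate(self):
        mu = 0.433
        t = np.arange(0, 121, 15.0)
        series = self._series(t, np.exp(-mu * t / 60.0))
        fit = pl.component_rate(series, "light", np.ones(len(t)))
        assert fit.slope == pytest.approx(-mu * LOG10E, abs=1e-9)  # -0.188
        assert -fit.slope == pytest.approx(0.188, abs=5e-4)

    def test_all_missing_component_is_absent(self):
        t = np.arange(0, 121, 15.0)
        series = self._series(t, np.exp(-0.4 * t / 60.0))
        fit = pl.component_rate(series, "heavy", np.ones(len(t)))
        assert not fit.defined

    def test_constant_relative_abundance_has_zero_slope(self):
        t = np.arange(0, 121, 15.0)
        series = self._series(t, np.full(len(t), 0.25))
        fit = pl.component_rate(series, "light", np.ones(len(t)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)


class TestSparseRatioRule:
    def _estimate(self, dis=0.2, prod=0.15):
        return pl.TurnoverEstimate(
            protein_id="P", disappearance_rate=dis, production_rate=prod,
        )

    def test_enough_ratios_leaves_estimate_unchanged(self):
        est = resolve_sparse_ratio(self._estimate(), 5, 0.8, 0.1)
        assert est.disappearance_rate == 0.2 and est.production_rate == 0.15

    def test_low_abundance_heavy_rate_discarded(self):
        est = resolve_sparse_ratio(self._estimate(), 3, 0.8, 0.1)
        assert est.disappearance_rate == 0.2
        assert est.production_rate is None

    def test_rule_requires_both_rates(self):
        est = resolve_sparse_ratio(self._estimate(prod=None), 3, 0.1, 0.8)
        assert est.disappearance_rate == 0.2


class TestClassification:
    def _estimates(self, half_lives):
        return [
            pl.TurnoverEstimate(protein_id=f"P{i}", disappearance_rate=0.1, half_life=h)
            for i, h in enumerate(half_lives)
        ]

    def test_hand_computed_mad_threshold(self):
        """median 102.5, MAD 1.4826*7.5 = 11.12, upper bound 124.7."""
        out, summary = pl.classify_vs_growth(self._estimates([90, 95, 100, 105, 110, 400]))
        labels = {e.protein_id: e.classification for e in out}
        assert labels["P5"] == "slower_than_growth"
        assert all(labels[f"P{i}"] == "dilution_by_growth" for i in range(5))
        assert summary.half_life_median == pytest.approx(102.5)
        assert summary.half_life_mad == pytest.approx(1.4826 * 7.5, rel=1e-3)

    def test_identical_half_lives_are_all_dilution(self):
        out, _ = pl.classify_vs_growth(self._estimates([100.0] * 5))
        assert all(e.classification == "dilution_by_growth" for e in out)

    def test_fewer_than_three_half_lives_unassessed(self):
        out, summary = pl.classify_vs_growth(self._estimates([100.0, 110.0]))
        assert all(e.classification == "unassessed" for e in out)
        assert summary.half_life_median is None


class TestPipeline:
    def test_row_order_invariance(self, glucose_shift_config, dilution_cohort):
        table = pl.simulate_labeling_experiment(glucose_shift_config, dilution_cohort)
        est1, sum1 = pl.run_turnover_pipeline(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        est2, sum2 = pl.run_turnover_pipeline(shuffled)
        pd.testing.assert_frame_equal(est1, est2)
        assert sum1 == sum2

    def test_analytic_limit_at_eight_point_design(self, clean_config):
        """Noiseless dilution-only input: the cohort median replacement time
        lands within 3% of the doubling time ln2/mu."""
        truths = [
            pl.ProteinTruth(protein_id=f"P{i:03d}", a0=1.0, a1=1.0)
            for i in range(clean_config.n_proteins)
        ]
        table = pl.simulate_labeling_experiment(clean_config, truths)
        _, summary = pl.run_turnover_pipeline(table)
        doubling = math.log(2) / clean_config.mu_post * 60.0
        assert summary.median_replacement_time == pytest.approx(doubling, rel=0.03)

    def test_replacement_time_decreases_with_induction_ratio(self):
        """Across noiseless proteins the fitted replacement time is strictly
        decreasing in the expression fold change a1/a0."""
        folds = [0.5, 1.0, 2.0, 4.0, 8.0]
        truths = [
            pl.ProteinTruth(protein_id=f"F{i}", a0=1.0, a1=f)
            for i, f in enumerate(folds)
        ] + [pl.ProteinTruth(protein_id=f"B{i:02d}", a0=1.0, a1=1.0) for i in range(40)]
        cfg = pl.SimulationConfig(
            n_proteins=len(truths), mu_post=0.433,
            sampling_times=tuple(range(15, 121, 15)),
            noise_cv=0.0, detection_limit=0.0, sample_scale_cv=0.0, seed=0,
        )
        est, _ = pl.run_turnover_pipeline(
            pl.simulate_labeling_experiment(cfg, truths)
        )
        est = est.set_index("protein_id")
        times = [est.loc[f"F{i}", "replacement_time_min"] for i in range(len(folds))]
        assert all(b < a for a, b in zip(times, times[1:]))

    def test_stagnated_production_yields_no_replacement_or_production(self):
        truths = [
            pl.ProteinTruth(protein_id=f"P{i:02d}", a0=1.0, a1=1.0, stagnation_time=0.0)
            for i in range(20)
        ]
        cfg = pl.SimulationConfig(
            n_proteins=20, mu_post=0.433, sampling_times=tuple(range(15, 121, 15)),
            noise_cv=0.0, detection_limit=0.0, sample_scale_cv=0.0, seed=0,
        )
        est, summary = pl.run_turnover_pipeline(
            pl.simulate_labeling_experiment(cfg, truths)
        )
        assert est["replacement_time_min"].isna().all()
        assert est["production_rate_log10_per_h"].isna().all()
        assert summary.n_replacement_models == 0

    def test_no_model_from_fewer_than_four_observations(self):
        """Gate soundness: < 4 usable ratio observations never yields a
        replacement model."""
        rows = []
        for t in (15.0, 30.0, 45.0):  # only three post-shift points
            rows.append(
                {"protein_id": "SPARSE", "sample": f"t{int(t)}", "time_min": t,
                 "intensity_L": 1e6, "intensity_H": 0.5e6, "ratio_HL": 0.5}
            )
        table = pd.DataFrame(rows)
        est, _ = pl.run_turnover_pipeline(table)
        assert est["replacement_time_min"].isna().all()
        assert est.loc[0, "replacement_absence_reason"] == "insufficient_points"

    def test_every_reported_model_meets_observation_gates(
        self, glucose_shift_config, dilution_cohort
    ):
        table = pl.simulate_labeling_experiment(glucose_shift_config, dilution_cohort)
        est, _ = pl.run_turnover_pipeline(table)
        with_model = est[est["replacement_time_min"].notna()]
        assert (with_model["n_hl_ratios"] >= 4).all()

    def test_median_replacement_bias_below_5pct_over_seeds(self):
        """Parameter recovery: at noise CV 0.2 and 600 proteins, the median
        replacement time is within 5% of the doubling time in every one of
        20 seeded replicates."""
        mu = 0.433
        doubling = math.log(2) / mu * 60.0
        medians = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            truths = pl.make_cohort(600, rng=rng)
            cfg = pl.SimulationConfig(
                n_proteins=600, mu_post=mu, sampling_times=tuple(range(15, 121, 15)),
                noise_cv=0.2, seed=2000 + seed,
            )
            _, summary = pl.run_turnover_pipeline(
                pl.simulate_labeling_experiment(cfg, truths)
            )
            medians.append(summary.median_replacement_time)
        assert np.all(np.abs(np.array(medians) / doubling - 1) < 0.05)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            pl.run_turnover_pipeline(pd.DataFrame())
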