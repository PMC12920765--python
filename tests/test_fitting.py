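import math

import numpy as np
import pandas as pd
import pytest

from cadkin import (
    ExposureSchedule,
    KineticParams,
    adjusted_r2,
    aic,
    asymptotic_ci,
    compare_nested,
    concentration_at_switch,
    fit_phase,
    phase_subset,
    pooled_config,
    schedule_from_data,
    generate_dataset,
)
from cadkin.fitting import FitResult, _aic_value


def grid_search_rss(tau, y, c0, c_e, lo=0.01, hi=10.0, n_grid=60, n_zoom=10):
    """Independent oracle: zooming 2-D grid search over (kA, kE).

    Uses its own curve formula, not the package's prediction path.
    """
    best = None
    lo_a, hi_a, lo_e, hi_e = lo, hi, lo, hi
    for _ in range(n_zoom):
        kas = np.linspace(lo_a, hi_a, n_grid)
        kes = np.linspace(lo_e, hi_e, n_grid)
        decay = np.exp(-kes[:, None] * tau[None, :])  # (kE, t)
        base = c0 * decay  # (kE, t)
        grow = (1.0 - decay) / kes[:, None]  # (kE, t)
        pred = base[None, :, :] + c_e * kas[:, None, None] * grow[None, :, :]
        rss = np.sum((pred - y[None, None, :]) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        best = (kas[i], kes[j], rss[i, j])
        da = (hi_a - lo_a) / (n_grid - 1)
        de = (hi_e - lo_e) / (n_grid - 1)
        lo_a, hi_a = max(lo, kas[i] - 3 * da), kas[i] + 3 * da
        lo_e, hi_e = max(lo, kes[j] - 3 * de), kes[j] + 3 * de
    return best


class TestZeroNoiseRecovery:
    def test_contamination_recovers_truth(self, noiseless_dataset):
        sched = ExposureSchedule(C_I0=2.0)
        fit = fit_phase(noiseless_dataset, "contamination", sched, "pooled")
        assert fit.estimates["kA1"] == pytest.approx(0.871, rel=1e-6)
        assert fit.estimates["kE1"] == pytest.approx(1.119, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_decontamination_recovers_truth(self, noiseless_dataset):
        sched = ExposureSchedule(C_I0=2.0)
        fit = fit_phase(noiseless_dataset, "decontamination", sched, "pooled")
        assert fit.estimates["kA2"] == pytest.approx(4.075, rel=1e-6)
        assert fit.estimates["kE2"] == pytest.approx(0.33, rel=1e-6)

    def test_zero_noise_ci_width_shrinks_to_zero(self, noiseless_dataset):
        sched = ExposureSchedule(C_I0=2.0)
        fit = fit_phase(noiseless_dataset, "contamination", sched, "pooled")
        lo, hi = fit.ci95["kA1"]
        assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_perfect_fit_adjusted_r2_is_one(self, noiseless_dataset):
        sched = ExposureSchedule(C_I0=2.0)
        fit = fit_phase(noiseless_dataset, "contamination", sched, "pooled")
        assert adjusted_r2(fit, noiseless_dataset) == pytest.approx(1.0, abs=1e-12)


class TestFitPhase:
    def test_habitat_symmetry_on_shared_truth(self):
        # both habitats generated from identical parameters
        cfg = pooled_config(seed=3, exceedance_prob=0.0)
        data = generate_dataset(cfg).observations
        sched = schedule_from_data(data)
        fit = fit_phase(data, "contamination", sched, "by_habitat")
        assert fit.estimates["kA1_city"] == pytest.approx(
            fit.estimates["kA1_forest"], rel=0.5
        )
        assert fit.n_params == 4

    def test_by_habitat_has_twice_the_parameters(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        pooled = fit_phase(default_dataset, "contamination", sched, "pooled")
        hab = fit_phase(default_dataset, "contamination", sched, "by_habitat")
        assert hab.n_params == 2 * pooled.n_params

    def test_nestedness_rss(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        for phase in ("contamination", "decontamination"):
            pooled = fit_phase(default_dataset, phase, sched, "pooled")
            hab = fit_phase(default_dataset, phase, sched, "by_habitat")
            assert hab.rss <= pooled.rss + 1e-9

    def test_start_point_robustness(self):
        cfg = pooled_config(seed=11, exceedance_prob=0.0)
        data = generate_dataset(cfg).observations
        sched = schedule_from_data(data)
        fit = fit_phase(data, "contamination", sched, "pooled")
        rss = [e["rss"] for e in fit.start_log if e["converged"]]
        assert len(rss) == 9  # full {0.1, 1, 5}^2 grid converged
        assert (max(rss) - min(rss)) / min(rss) < 1e-8

    def test_gauss_newton_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        sched = ExposureSchedule(C_I0=2.0)
        days = np.array([1, 3, 5, 10, 15, 21], dtype=float)
        tau = np.repeat(days, 2)
        truth = KineticParams(0.9, 1.1)
        decay = np.exp(-truth.kE * tau)
        y = 2.0 * decay + 100 * truth.kA / truth.kE * (1 - decay)
        y = y + rng.normal(0, 5, size=tau.size)
        data = pd.DataFrame(
            {
                "colony_id": [f"G{i}" for i in range(tau.size)],
                "habitat": "forest",
                "region": "paris",
                "time_days": tau,
                "concentration": np.clip(y, 0, None),
            }
        )
        fit = fit_phase(data, "contamination", sched, "pooled")
        _, _, rss_grid = grid_search_rss(tau, data["concentration"].to_numpy(), 2.0, 100.0)
        assert fit.rss <= rss_grid * (1 + 1e-9)
        assert abs(rss_grid - fit.rss) / fit.rss < 1e-6

    def test_decontamination_anchor_recorded(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "decontamination", sched, "pooled")
        assert fit.anchor == "pooled"
        pooled1 = fit_phase(default_dataset, "contamination", sched, "pooled")
        assert fit.c_switch == pytest.approx(
            concentration_at_switch(pooled1.params(), sched)
        )

    def test_habitat_specific_anchor_option(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(
            default_dataset, "decontamination", sched, "by_habitat", anchor="by_habitat"
        )
        assert fit.anchor == "by_habitat"
        assert set(fit.c_switch) == {"city", "forest"}

    def test_too_few_time_points_rejected(self, schedule):
        data = pd.DataFrame(
            {
                "colony_id": ["a", "b"],
                "habitat": ["forest", "city"],
                "region": ["paris", "paris"],
                "time_days": [1.0, 3.0],
                "concentration": [10.0, 20.0],
            }
        )
        with pytest.raises(ValueError, match="distinct time"):
            fit_phase(data, "contamination", schedule, "pooled")

    def test_missing_habitat_level_rejected(self, schedule):
        data = pd.DataFrame(
            {
                "colony_id": list("abcdef"),
                "habitat": "forest",
                "region": "paris",
                "time_days": [1.0, 3.0, 5.0, 10.0, 15.0, 21.0],
                "concentration": [30.0, 60, 70, 75, 78, 77],
            }
        )
        with pytest.raises(ValueError, match="both habitat"):
            fit_phase(data, "contamination", schedule, "by_habitat")

    def test_day_zero_rows_excluded_from_contamination(self, noiseless_dataset):
        sched = ExposureSchedule(C_I0=2.0)
        sub = phase_subset(noiseless_dataset, "contamination", sched)
        assert sub["time_days"].min() > 0
        assert sub["time_days"].max() <= 21
        fit = fit_phase(noiseless_dataset, "contamination", sched, "pooled")
        assert fit.n_obs == len(sub) == 48

    def test_nonpositive_estimates_flagged_not_clipped(self, schedule):
        # decreasing "uptake" data pushes kA below zero
        rng = np.random.default_rng(0)
        days = np.repeat([1.0, 3, 5, 10, 15, 21], 2)
        y = np.clip(2.0 - 0.05 * days + rng.normal(0, 0.05, days.size), 0.01, None)
        data = pd.DataFrame(
            {
                "colony_id": [f"w{i}" for i in range(days.size)],
                "habitat": "forest",
                "region": "paris",
                "time_days": days,
                "concentration": y,
            }
        )
        fit = fit_phase(data, "contamination", schedule, "pooled")
        if any(v <= 0 for v in fit.estimates.values()):
            assert any("non-positive" in w for w in fit.warnings)


class TestAsymptoticCI:
    def test_formula_matches_hand_computation(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "contamination", sched, "pooled")
        from scipy import stats as ss

        cov = np.linalg.inv(fit._jtj) * (fit.rss / (fit.n_obs - fit.n_params))
        q = ss.t.ppf(0.975, fit.n_obs - fit.n_params)
        se = math.sqrt(cov[0, 0])
        lo, hi = fit.ci95["kA1"]
        assert lo == pytest.approx(fit.estimates["kA1"] - q * se, rel=1e-10)
        assert hi == pytest.approx(fit.estimates["kA1"] + q * se, rel=1e-10)

    def test_z_quantile_option_narrower(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "contamination", sched, "pooled")
        zfit = asymptotic_ci(fit, level=0.95, quantile="z")
        t_lo, t_hi = fit.ci95["kA1"]
        z_lo, z_hi = zfit.ci95["kA1"]
        assert (z_hi - z_lo) < (t_hi - t_lo)

    def test_level_changes_width(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "contamination", sched, "pooled")
        wide = asymptotic_ci(fit, level=0.99)
        assert (wide.ci95["kA1"][1] - wide.ci95["kA1"][0]) > (
            fit.ci95["kA1"][1] - fit.ci95["kA1"][0]
        )


class TestAdjustedR2:
    def test_constant_mean_prediction_nonpositive(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "contamination", sched, "pooled")
        sub = phase_subset(default_dataset, "contamination", sched)
        y = sub["concentration"].to_numpy()
        # a fit whose rss equals tss must score <= 0 after the df penalty
        fake = FitResult(
            phase=fit.phase, grouping="pooled", estimates={}, se={}, ci95={},
            rss=float(np.sum((y - y.mean()) ** 2)), n_obs=len(y), n_params=2,
            adjusted_r2=0.0, aic=0.0, converged=True, n_iterations=0,
            schedule=sched,
        )
        assert adjusted_r2(fake, default_dataset) <= 0.0

    def test_matches_fit_attribute(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "contamination", sched, "pooled")
        assert adjusted_r2(fit, default_dataset) == pytest.approx(fit.adjusted_r2)


class TestAIC:
    def test_equal_rss_equal_p_equal_aic(self):
        assert _aic_value(10.0, 20, 2) == _aic_value(10.0, 20, 2)

    def test_hand_formula_on_toy_fit(self):
        # stored 6-point toy fit: n = 6, p = 2, rss = 3.5
        n, p, rss = 6, 2, 3.5
        expected = n * math.log(2 * math.pi * rss / n) + n + 2 * (p + 1)
        assert _aic_value(rss, n, p) == pytest.approx(expected, abs=1e-9)

    def test_zero_rss_errors(self):
        with pytest.raises(ValueError, match="rss = 0"):
            _aic_value(0.0, 6, 2)

    def test_aic_operation_on_fit(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        fit = fit_phase(default_dataset, "contamination", sched, "pooled")
        assert aic(fit) == pytest.approx(fit.aic)


class TestCompareNested:
    def test_identical_rss_gives_f_zero_p_one(self, schedule):
        key = np.zeros((3, 3))
        base = dict(
            estimates={}, se={}, ci95={}, rss=5.0, n_obs=20,
            adjusted_r2=0.5, aic=100.0, converged=True, n_iterations=3,
            schedule=schedule, _data_key=key,
        )
        null = FitResult(phase="contamination", grouping="pooled", n_params=2, **base)
        alt = FitResult(
            phase="contamination", grouping="by_habitat", n_params=4, **base
        )
        cmp = compare_nested(null, alt)
        assert cmp.f_stat == 0.0
        assert cmp.p_value == 1.0
        assert cmp.df_num == 2
        assert cmp.df_den == 16

    def test_real_comparison_consistency(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        null = fit_phase(default_dataset, "contamination", sched, "pooled")
        alt = fit_phase(default_dataset, "contamination", sched, "by_habitat")
        cmp = compare_nested(null, alt)
        f_hand = ((null.rss - alt.rss) / 2) / (alt.rss / (alt.n_obs - 4))
        assert cmp.f_stat == pytest.approx(f_hand)
        assert 0.0 <= cmp.p_value <= 1.0
        assert cmp.preferred in ("pooled", "by_habitat")
        assert cmp.preferred == (
            "by_habitat" if alt.aic < null.aic else "pooled"
        )

    def test_mismatched_phases_rejected(self, default_dataset):
        sched = schedule_from_data(default_dataset)
        cont = fit_phase(default_dataset, "contamination", sched, "pooled")
        dec = fit_phase(default_dataset, "decontamination", sched, "by_habitat")
        with pytest.raises(ValueError, match="different phases"):
            compare_nested(cont, dec)

    def test_mismatched_data_rejected(self):
        sched = ExposureSchedule(C_I0=2.0)
        d1 = generate_dataset(pooled_config(seed=1)).observations
        d2 = generate_dataset(pooled_config(seed=2)).observations
        f1 = fit_phase(d1, "contamination", sched, "pooled")
        f2 = fit_phase(d2, "contamination", sched, "by_habitat")
        with pytest.raises(ValueError, match="different observations"):
            compare_nested(f1, f2)
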