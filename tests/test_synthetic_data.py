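import numpy as np
import pytest
from scipy.optimize import brentq

import foxdepletion as fx
from foxdepletion.calendars import STEPS_PER_YEAR
from foxdepletion.schedules import RecruitmentSchedule
from foxdepletion.synthetic_data import (
    EffortPattern,
    OperatingTruth,
    check_data_requirements,
    generate_effort,
    simulate_estate,
)


class TestGenerateEffort:
    def test_no_noise_no_attenuation_constant_within_season(self):
        pattern = EffortPattern(weekly_hours=(3, 3, 3, 3),
                                summer_attenuation=1.0, noise_cv=0.0, years=1)
        e = generate_effort(pattern, seed=0)
        assert np.allclose(e, 6.0)  # 2 weeks x 3 hr/wk

    def test_summer_attenuation_lowers_summer_steps(self):
        pattern = EffortPattern(weekly_hours=(3, 3, 3, 3),
                                summer_attenuation=0.5, noise_cv=0.0, years=1)
        e = generate_effort(pattern, seed=0)
        assert np.allclose(e[11:17], 3.0)  # summer steps 12-17
        assert np.allclose(np.delete(e, np.s_[11:17]), 6.0)

    def test_deterministic_for_fixed_seed(self):
        pattern = EffortPattern(years=3)
        assert np.array_equal(generate_effort(pattern, 5),
                              generate_effort(pattern, 5))

    def test_gap_yields_zero_steps(self):
        pattern = EffortPattern(years=2, gap=(10, 20))
        e = generate_effort(pattern, seed=1)
        assert np.all(e[10:30] == 0)


class TestSimulateEstate:
    def test_zero_search_rate_means_no_detections(self, sched):
        truth = OperatingTruth(params=fx.ModelParams(
            N0=2, K=4, v=0.2, r=3.0, M=0.013, d=1e-300))
        effort = generate_effort(EffortPattern(years=3), seed=2)
        series, _ = simulate_estate(truth, effort, sched, seed=3)
        assert series.Y.sum() == 0
        assert series.L.sum() == 0

    def test_lamping_cull_never_exceeds_detections(self, standard_estate):
        series, _ = standard_estate
        assert np.all(series.L * series.area <= series.Y + 1e-9)

    def test_detection_rate_recovers_search_rate(self, sched):
        # mean of Y_t / (E_t N_t) estimates d by the law of large numbers
        d = 0.45
        truth = OperatingTruth(
            params=fx.ModelParams(N0=2, K=4, v=0.2, r=3.0, M=0.013, d=d,
                                  sigma_p=0.05),
            kill_prob=0.0, other_cull_ratio=0.0, cub_cull_fraction=0.0)
        effort = generate_effort(
            EffortPattern(weekly_hours=(5, 5, 5, 5), summer_attenuation=1.0,
                          noise_cv=0.0, years=8), seed=4)
        series, traj = simulate_estate(truth, effort, sched, seed=5)
        ratio = series.Y / (series.E * traj.N)
        se = ratio.std(ddof=1) / np.sqrt(len(ratio))
        assert ratio.mean() == pytest.approx(d, abs=4 * se)

    def test_unculled_population_approaches_fixed_point(self, sched):
        # with uniform recruitment weights and no culling the dynamics have a
        # positive fixed point: N e^-M + v(1-N/K) + (r/26) N (1-N/K) = N
        p = fx.ModelParams(N0=1.0, K=4.0, v=0.2, r=3.0, M=0.013, d=1e-300,
                           sigma_p=1e-6)
        truth = OperatingTruth(params=p, kill_prob=0.0, other_cull_ratio=0.0,
                               cub_cull_fraction=0.0)
        uniform = RecruitmentSchedule(np.full(STEPS_PER_YEAR,
                                              1 / STEPS_PER_YEAR))
        effort = np.zeros(26 * 12)
        _, traj = simulate_estate(truth, effort, uniform, seed=6)

        def balance(N):
            return (N * np.exp(-p.M) + p.v * (1 - N / p.K)
                    + p.r / 26 * N * (1 - N / p.K) - N)

        n_star = brentq(balance, 0.01, p.K)
        assert traj.N[-1] == pytest.approx(n_star, rel=1e-3)

    def test_cub_cull_redistributed_mass_conserved(self, standard_estate):
        series, _ = standard_estate
        # observed cub culls recorded only at the first recruitment step
        nz = np.nonzero(series.C_obs)[0]
        assert all(series.steps[i] == 9 for i in nz)


class TestDataRequirements:
    def test_standard_estate_passes_cleanly(self, sched, standard_estate):
        series, _ = standard_estate
        report = check_data_requirements(series, sched)
        assert report.passed
        assert report.reasons == []

    def test_two_recruitment_periods_fail(self, sched, standard_truth):
        effort = generate_effort(EffortPattern(years=2), seed=7)
        series, _ = simulate_estate(standard_truth, effort, sched, seed=8)
        report = check_data_requirements(series, sched)
        assert not report.passed
        assert any("recruitment periods" in r for r in report.reasons)

    def test_long_gap_fails_nine_month_rule(self, sched, standard_truth):
        effort = generate_effort(
            EffortPattern(years=4, gap=(30, 20)), seed=9)
        series, _ = simulate_estate(standard_truth, effort, sched, seed=10)
        report = check_data_requirements(series, sched)
        assert not report.checks["max_gap"]
        assert any("nine months" in r for r in report.reasons)

    def test_no_effort_in_recruitment_period_fails(self, sched,
                                                   standard_truth):
        effort = generate_effort(EffortPattern(years=4), seed=11)
        w_steps = np.nonzero(sched.w)[0] + 1
        _, steps = (np.arange(len(effort)) // 26,
                    np.arange(len(effort)) % 26 + 1)
        effort = np.where(np.isin(steps, w_steps), 0.0, effort)
        series, _ = simulate_estate(standard_truth, effort, sched, seed=12)
        report = check_data_requirements(series, sched)
        assert not report.checks["recruitment_effort"]

    def test_invalid_truth_parameters_rejected(self):
        with pytest.raises(ValueError, match="kill_prob"):
            OperatingTruth(params=fx.ModelParams(
                N0=2, K=4, v=0.2, r=3, M=0.01, d=0.5), kill_prob=1.5)
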