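import numpy as np
import pandas as pd
import pytest

from maskddm.design import DEADLINE_S, build_design
from maskddm.engine import EngineConfig, solve_fptd, upper_absorption_probability
from maskddm.models import DDMParams, GROUP_MEANS, GROUP_SDS
from maskddm.simulate import (CohortSpec, draw_cohort_params,
                              simulate_condition, simulate_cohort,
                              simulate_participant, simulate_trial)

# a parameter set with no mask effects and no collapse, for closed forms
FLAT = DDMParams(a=0.5, tau=0.0, ter0=0.2, ter_mask=0.0, vc0=0.0, vc_mask=0.0,
                 v_slope0=0.0, v_slope_mask=0.0, z0=0.0, z_mask=0.0)


class TestSimulateCondition:
    def test_symmetric_process_splits_evenly(self):
        rng = np.random.default_rng(0)
        ch, _ = simulate_condition(FLAT, 0, 0, 100_000, rng)
        decided = ch[ch >= 0]
        assert len(decided) > 99_000
        assert (decided == 1).mean() == pytest.approx(0.5, abs=0.01)

    def test_constant_bound_absorption_matches_closed_form(self):
        # drift 1 toward the upper bound at +-0.5: P(upper) ~ 0.731
        p = DDMParams(a=0.5, tau=0.0, ter0=0.2, ter_mask=0.0, vc0=1.0,
                      vc_mask=0.0, v_slope0=0.0, v_slope_mask=0.0,
                      z0=0.0, z_mask=0.0)
        rng = np.random.default_rng(1)
        ch, _ = simulate_condition(p, 0, 0, 100_000, rng)
        target = upper_absorption_probability(1.0, 0.5, 0.0)
        assert (ch == 1).mean() == pytest.approx(target, abs=0.01)

    def test_rt_bounds_and_miss_coding(self):
        rng = np.random.default_rng(2)
        ch, rt = simulate_condition(GROUP_MEANS, 1, 10, 5000, rng)
        ok = ch >= 0
        assert np.isnan(rt[~ok]).all()
        assert (rt[ok] <= DEADLINE_S + 1e-9).all()
        assert (rt[ok] > GROUP_MEANS.ter0).all()

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            simulate_condition(FLAT, 0, 0, 10, np.random.default_rng(0), dt=0.0)

    def test_sampler_matches_solver_distribution(self):
        """Kolmogorov-Smirnov agreement between the path sampler and the
        (refined-grid) density solver, per choice, at 1e5 draws."""
        from maskddm._kernels import em_sample
        v, a, tau, z = 0.17 + 0.4 * 5.68, 1.08, 1.29, -0.06
        ch, td = em_sample(v, a, tau, z * a, 0.001, 2.3, 100_000, 99)
        f = solve_fptd(v, a, tau, z, EngineConfig(dt=0.001, dx=0.002))
        for side in (1, 0):
            dens = f.upper_density if side else f.lower_density
            t_emp = np.sort(td[ch == side])
            n = len(t_emp)
            cdf = np.cumsum(dens) * f.dt / (dens.sum() * f.dt)
            gap = np.interp(t_emp, f.time_grid, cdf) - (np.arange(1, n + 1) - 0.5) / n
            assert np.abs(gap).max() < 0.025
            # absorption probability agreement, same draw
            assert (ch == side).mean() == pytest.approx(
                f.prob_upper() if side else f.prob_lower(), abs=0.01)


class TestSimulateParticipant:
    def test_one_record_per_design_trial(self, small_participant, session_design):
        assert len(small_participant) == len(session_design) == 608
        assert small_participant["choice"].isin(["unfriendly", "friendly", "miss"]).all()
        assert (small_participant["choice"].eq("miss").mean()) < 0.05

    def test_choice_fraction_monotone_in_emotion(self, medium_participant):
        t = medium_participant[medium_participant["choice"] != "miss"]
        frac = (t.groupby("emotion")["choice"]
                  .apply(lambda c: c.eq("unfriendly").mean()))
        assert np.all(np.diff(frac.sort_index().to_numpy()) > -0.02)

    def test_extreme_start_bias_dominates_masked_choices(self, session_design):
        from dataclasses import replace
        p = replace(GROUP_MEANS, z0=0.0, z_mask=0.9)
        t = simulate_participant(p, session_design, seed=5)
        masked = t[(t["mask"] == 1) & (t["choice"] != "miss")]
        assert masked["choice"].eq("unfriendly").mean() > 0.9

    def test_reproducible_given_seed(self, group_mean_params, session_design):
        a = simulate_participant(group_mean_params, session_design, seed=9)
        b = simulate_participant(group_mean_params, session_design, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_trial_wrapper(self, group_mean_params):
        rng = np.random.default_rng(3)
        choice, rt = simulate_trial(group_mean_params, 1, 40, rng)
        assert choice in {"unfriendly", "friendly", "miss"}
        assert (choice == "miss") == np.isnan(rt)


class TestCohort:
    def test_defaults_encode_study_conditions(self):
        spec = CohortSpec()
        assert spec.n_participants == 136
        assert spec.means == GROUP_MEANS and spec.sds == GROUP_SDS

    def test_zero_sds_give_identical_participants(self):
        zero = DDMParams(**dict.fromkeys(GROUP_SDS.to_dict(), 0.0))
        spec = CohortSpec(n_participants=3, sds=zero, seed=1)
        draws = draw_cohort_params(spec)
        assert all(p == GROUP_MEANS for p in draws)

    def test_draws_respect_truncation_and_seed(self):
        spec = CohortSpec(n_participants=5, seed=42)
        draws = draw_cohort_params(spec)
        assert draws == draw_cohort_params(spec)
        for p in draws:
            p.validate()
            assert p.tau > 0

    def test_infeasible_truncation_raises(self):
        bad_means = DDMParams(z0=0.995, z_mask=0.9)
        zero = DDMParams(**dict.fromkeys(GROUP_SDS.to_dict(), 0.0))
        with pytest.raises((RuntimeError, ValueError)):
            draw_cohort_params(CohortSpec(n_participants=1, means=bad_means,
                                          sds=zero))
        with pytest.raises(ValueError):
            CohortSpec(n_participants=0)

    def test_small_cohort_end_to_end(self):
        trials, truths = simulate_cohort(CohortSpec(n_participants=2, seed=3))
        assert len(truths) == 2
        assert trials["participant"].nunique() == 2
        assert (trials.groupby("participant").size() == 608).all()
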