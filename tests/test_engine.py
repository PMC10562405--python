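import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maskddm.engine import (EngineConfig, LIKELIHOOD_FLOOR,
                            analytic_fptd_constant_bounds, bound, solve_fptd,
                            trial_loglik, upper_absorption_probability)

# parameter sets spanning drift sign, collapse and start-point offsets
PARAM_GRID = [
    (0.0, 1.0, 0.0, 0.0),
    (1.0, 0.5, 0.0, 0.0),
    (3.578, 1.08, 1.29, -0.06),
    (-2.45, 1.08, 1.29, 0.04),
    (0.5, 1.5, 2.0, 0.3),
    (-1.0, 0.8, 0.5, -0.2),
]


class TestBound:
    def test_collapse_evaluation(self):
        assert bound(1.08, 1.29, 0.0) == pytest.approx(1.08)
        assert bound(1.08, 1.29, 1.0) == pytest.approx(1.08 * np.exp(-1.29))
        assert bound(1.08, 0.0, 5.0) == pytest.approx(1.08)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bound(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            bound(1.0, -1.0, 0.0)


class TestEngineConfig:
    def test_rejects_nonpositive_steps(self):
        for kw in ({"dt": 0.0}, {"dx": -1e-3}, {"t_max": 0.0}):
            with pytest.raises(ValueError):
                EngineConfig(**kw)


class TestSolver:
    @pytest.mark.parametrize("v,a,tau,z", PARAM_GRID)
    def test_probability_conservation(self, v, a, tau, z):
        f = solve_fptd(v, a, tau, z)
        assert f.total_probability() == pytest.approx(1.0, abs=1e-3)
        assert (f.upper_density >= -1e-9).all()
        assert (f.lower_density >= -1e-9).all()

    def test_symmetric_null_process(self):
        f = solve_fptd(0.0, 1.0, 0.0, 0.0)
        np.testing.assert_allclose(f.upper_density, f.lower_density, atol=1e-10)
        total = f.prob_upper() + f.prob_lower()
        assert f.prob_upper() / total == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("v,a,z", [(1.0, 0.5, 0.0), (2.0, 0.8, 0.2),
                                       (-1.0, 0.9, 0.1)])
    def test_absorption_probability_closed_form(self, v, a, z):
        f = solve_fptd(v, a, 0.0, z, EngineConfig(t_max=8.0))
        assert f.prob_upper() == pytest.approx(
            upper_absorption_probability(v, a, z), abs=2e-3)

    def test_constant_bound_closed_form_value(self):
        # P(upper) = 1 / (1 + exp(-2*v*a)) for v=1, a=0.5 is about 0.731
        assert upper_absorption_probability(1.0, 0.5, 0.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)))

    def test_mean_first_passage_time_zero_drift(self):
        # E[T] = a^2 for zero drift, symmetric constant bounds, unit noise
        f = solve_fptd(0.0, 1.0, 0.0, 0.0, EngineConfig(t_max=12.0))
        mean = float(((f.upper_density + f.lower_density) * f.time_grid).sum() * f.dt)
        assert mean == pytest.approx(1.0, abs=5e-3)

    def test_start_point_near_boundary_raises(self):
        with pytest.raises(ValueError):
            solve_fptd(0.0, 1.0, 0.0, 0.999)
        with pytest.raises(ValueError):
            solve_fptd(0.0, 1.0, 0.0, 1.2)

    def test_refinement_convergence(self):
        """Halving dt and dx moves the choice probability by < 1e-3."""
        for v, a, tau, z in [(3.578, 1.08, 1.29, -0.06), (0.5, 1.0, 0.5, 0.2)]:
            p1 = solve_fptd(v, a, tau, z).prob_upper()
            p2 = solve_fptd(v, a, tau, z, EngineConfig(dt=0.0025, dx=0.0025)).prob_upper()
            assert abs(p1 - p2) < 1e-3

    def test_upper_probability_monotone_in_drift_and_start(self):
        probs_v = [solve_fptd(v, 1.0, 1.0, 0.0).prob_upper()
                   for v in (-2, -1, 0, 1, 2)]
        assert np.all(np.diff(probs_v) > 0)
        probs_z = [solve_fptd(0.5, 1.0, 1.0, z).prob_upper()
                   for z in (-0.5, -0.2, 0.0, 0.2, 0.5)]
        assert np.all(np.diff(probs_z) > 0)


class TestAnalyticOracle:
    @pytest.mark.parametrize("v,a,z", [(0.0, 1.0, 0.0), (1.0, 0.5, 0.0),
                                       (2.0, 0.8, 0.2), (-1.5, 1.2, -0.3)])
    def test_solver_matches_series_solution(self, v, a, z):
        """Constant-bound solver agrees with the eigenfunction series.

        Sup-norm tolerance: 2% of the series' peak density plus a small
        absolute term covering the solver's early-time transient.
        """
        f = solve_fptd(v, a, 0.0, z, EngineConfig(t_max=4.0))
        an = analytic_fptd_constant_bounds(v, a, z, f.time_grid)
        for side in ("upper_density", "lower_density"):
            diff = np.abs(getattr(an, side) - getattr(f, side)).max()
            peak = getattr(an, side).max()
            assert diff <= 0.02 * peak + 5e-3

    def test_series_integral_matches_closed_form(self):
        t = np.arange(1, 4000) * 0.002
        an = analytic_fptd_constant_bounds(2.0, 0.8, 0.2, t)
        assert an.prob_upper() == pytest.approx(
            upper_absorption_probability(2.0, 0.8, 0.2), abs=1e-3)

    def test_start_near_threshold_concentrates_mass(self):
        # fine grid: most mass escapes within a few milliseconds
        t = np.arange(1, 40_000) * 5e-5
        an = analytic_fptd_constant_bounds(0.0, 1.0, 0.95, t, n_terms=2000)
        assert an.prob_upper() > 0.95
        mean_upper = float((an.upper_density * t).sum() * 5e-5) / an.prob_upper()
        assert mean_upper < 0.2

    def test_truncation_error_raises(self):
        with pytest.raises(ValueError):
            analytic_fptd_constant_bounds(0.0, 1.0, 0.0,
                                          np.array([1e-5]), n_terms=5)
        with pytest.raises(ValueError):
            analytic_fptd_constant_bounds(0.0, 1.0, 0.0, np.array([-0.1, 0.1]))


class TestTrialLoglik:
    def test_symmetric_process_scores_choices_equally(self):
        f = solve_fptd(0.0, 1.0, 0.0, 0.0)
        assert trial_loglik(f, 0.3, 1, 0.8) == pytest.approx(
            trial_loglik(f, 0.3, 0, 0.8))

    def test_out_of_support_rt_hits_floor_not_minus_inf(self):
        f = solve_fptd(1.0, 1.0, 1.0, 0.0)
        floor = np.log(LIKELIHOOD_FLOOR)
        assert trial_loglik(f, 0.3, 1, 0.2) == pytest.approx(floor)   # rt < Ter
        assert trial_loglik(f, 0.3, 1, 99.0) == pytest.approx(floor)  # beyond t_max
        assert np.isfinite(trial_loglik(f, 0.3, 1, 0.8))

    def test_generating_parameters_beat_perturbed_drift(self, medium_participant):
        """The summed log-likelihood is higher under the generating
        parameters than under a clearly perturbed drift slope."""
        from maskddm.inference import _analyzable, _cell_data, _dataset_loglik
        from maskddm.models import MODEL_FAMILY, GROUP_MEANS
        from dataclasses import replace

        cells = _cell_data(_analyzable(medium_participant))
        spec = MODEL_FAMILY["full_vc_z"]
        cfg = EngineConfig()
        ll_true = _dataset_loglik(GROUP_MEANS.to_array(), spec, cells, cfg)
        ll_pert = _dataset_loglik(
            replace(GROUP_MEANS, v_slope0=3.5).to_array(), spec, cells, cfg)
        assert ll_true > ll_pert
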