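import numpy as np
import pandas as pd
import pytest

from maskddm.design import balanced_design
from maskddm.inference import (FitResult, FitSettings, fit_all_models,
                               fit_mle, goodness_of_fit, parameter_recovery,
                               select_models)
from maskddm.models import DDMParams, MODEL_FAMILY, GROUP_MEANS
from maskddm.simulate import simulate_participant

FAST = FitSettings.fast(seed=1)


def make_result(pid, model, loglik, n_trials=576):
    spec = MODEL_FAMILY[model]
    k = spec.n_free
    return FitResult(
        participant_id=pid, model=model, params=spec.pin(GROUP_MEANS),
        loglik=loglik, n_free_params=k, n_trials=n_trials,
        aic=2 * k - 2 * loglik, bic=k * np.log(n_trials) - 2 * loglik,
        seed=0, n_evaluations=1, converged=True)


@pytest.fixture(scope="module")
def family_fits(small_participant):
    """All four models fitted to one synthetic participant (fast preset)."""
    return fit_all_models(small_participant, FAST)


class TestFitMLE:
    def test_information_criteria_identities(self, family_fits):
        for f in family_fits:
            assert f.aic == pytest.approx(2 * f.n_free_params - 2 * f.loglik)
            assert f.bic == pytest.approx(
                f.n_free_params * np.log(f.n_trials) - 2 * f.loglik)
            assert f.n_trials <= 576  # 608 minus fillers and misses

    def test_nested_loglik_ordering(self, family_fits):
        ll = {f.model: f.loglik for f in family_fits}
        assert ll["full_vc_z"] >= ll["reduced_vc"] >= ll["null"]
        assert ll["full_vc_z"] >= ll["reduced_z"] >= ll["null"]

    def test_pinned_parameters_stay_zero(self, family_fits):
        by = {f.model: f for f in family_fits}
        assert by["null"].params.vc_mask == 0.0
        assert by["null"].params.z_mask == 0.0
        assert by["reduced_vc"].params.z_mask == 0.0
        assert by["reduced_z"].params.vc_mask == 0.0

    def test_deterministic_given_seed(self, small_participant):
        a = fit_mle(small_participant, MODEL_FAMILY["null"], FAST)
        b = fit_mle(small_participant, MODEL_FAMILY["null"], FAST)
        assert a == b

    def test_recovers_drift_slope_from_null_truth(self):
        """Refitting data generated under the null model recovers the
        drift slope to within 5% at ten thousand trials."""
        truth = DDMParams(vc_mask=0.0, z_mask=0.0)
        design = balanced_design(834, seed=21)  # ~1e4 trials
        trials = simulate_participant(truth, design, seed=22)
        fit = fit_mle(trials, MODEL_FAMILY["null"], FitSettings(seed=23))
        assert fit.converged
        assert fit.params.v_slope0 == pytest.approx(truth.v_slope0, rel=0.05)

    def test_empty_cell_raises(self, small_participant):
        broken = small_participant[small_participant["emotion"] != 40]
        with pytest.raises(ValueError):
            fit_mle(broken, MODEL_FAMILY["null"], FAST)


class TestSelectModels:
    def test_winner_percentages_and_means(self):
        fits = []
        for pid in (1, 2, 3):
            fits += [make_result(pid, "null", 100.0),
                     make_result(pid, "reduced_vc", 101.0),
                     make_result(pid, "reduced_z", 100.5),
                     make_result(pid, "full_vc_z", 112.0)]
        table = select_models(fits)
        aic = table[table.criterion == "AIC"].set_index("model")
        assert aic.loc["full_vc_z", "pct_best"] == 100.0
        assert aic["pct_best"].sum() == pytest.approx(100.0)
        bic = table[table.criterion == "BIC"].set_index("model")
        assert bic["pct_best"].sum() == pytest.approx(100.0)
        assert aic.loc["null", "mean"] == pytest.approx(2 * 8 - 2 * 100.0)

    def test_ties_go_to_fewest_parameters(self):
        fits = [make_result(1, m, 100.0 - (MODEL_FAMILY[m].n_free - 8))
                for m in MODEL_FAMILY]  # identical AIC for all four
        table = select_models(fits)
        aic = table[table.criterion == "AIC"].set_index("model")
        assert aic.loc["null", "pct_best"] == 100.0

    def test_incomplete_participant_excluded_with_warning(self):
        fits = [make_result(1, m, 100.0) for m in MODEL_FAMILY]
        fits += [make_result(2, "null", 90.0)]
        with pytest.warns(UserWarning):
            table = select_models(fits)
        assert table[table.criterion == "AIC"]["pct_best"].sum() == 100.0
        # no participant with a complete set of the fitted models
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            select_models([make_result(3, "null", 1.0),
                           make_result(4, "full_vc_z", 1.0)])

    def test_true_full_model_wins_aic_on_strongly_biased_cohort(self):
        """With large true mask biases and plenty of trials, AIC prefers
        the full model over the null for the simulated participant."""
        from dataclasses import replace
        truth = replace(GROUP_MEANS, vc_mask=-0.9, z_mask=0.25)
        design = balanced_design(120, seed=31)
        trials = simulate_participant(truth, design, seed=32)
        fits = fit_all_models(trials, FAST, participant_id=1)
        table = select_models(fits)
        aic = table[table.criterion == "AIC"].set_index("model")
        assert aic.loc["full_vc_z", "pct_best"] == 100.0


@pytest.fixture(scope="module")
def gof(medium_participant):
    """Truth-parameter predictions scored against their own data."""
    fake_fit = make_result(1, "full_vc_z", 0.0)
    return goodness_of_fit(fake_fit, medium_participant)


class TestGoodnessOfFit:
    def test_predictions_near_empirical_under_truth(self, gof):
        """Scoring the generating parameters against their own simulated
        data puts choice proportions and RT quantiles on the identity
        line, up to sampling noise."""
        r = gof.dropna(subset=["p_unfriendly_emp"])
        assert np.abs(r["p_unfriendly_emp"] - r["p_unfriendly_pred"]).max() < 0.03
        big = r[r["n"] > 200]
        for q in (10, 30, 50, 70, 90):
            assert np.abs(big[f"emp_q{q}"] - big[f"pred_q{q}"]).max() < 0.05

    def test_empirical_quantiles_monotone(self, gof):
        cols = [f"emp_q{q}" for q in (5, 10, 30, 50, 70, 90)]
        vals = gof.dropna(subset=cols)[cols].to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()

    def test_unconverged_fit_rejected(self, medium_participant):
        bad = make_result(1, "full_vc_z", 0.0)
        bad = FitResult(**{**bad.__dict__, "converged": False})
        with pytest.raises(ValueError):
            goodness_of_fit(bad, medium_participant)


class TestParameterRecovery:
    def test_harness_shapes_and_convergence(self):
        summary, per_rep = parameter_recovery(
            GROUP_MEANS, n_per_cell=120, n_reps=2, seed=9, settings=FAST)
        assert len(summary) == 10
        assert set(per_rep.columns) >= {"rep", "converged", "loglik"}
        assert (summary["n_reps"] <= 2).all()
        assert np.isfinite(summary["rmse"]).all()

    def test_rejects_nonpositive_reps(self):
        with pytest.raises(ValueError):
            parameter_recovery(GROUP_MEANS, n_per_cell=10, n_reps=0)
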