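import numpy as np
import pytest

from smaddecode.fitting import (
    ExpressionTimeCourse,
    FitResult,
    chi2,
    chi2_test,
    classify_simple,
    fit_ffl_cascade,
    fit_gene,
    _lhs_starts,
    _make_objective,
    _refine_starts,
)
from smaddecode.ode_models import SimpleModelParams, get_model, hill
from smaddecode.synthetic_data import add_noise, simulate_gene_panel


def make_tc(gene_id, smad, model_id, theta, times):
    spec = get_model(model_id)
    doses, tt, fc = [], [], []
    for dose, tr in smad.items():
        y = spec.simulate(theta, tr, times)
        doses += [dose] * times.size
        tt += list(times)
        fc += list(y)
    return ExpressionTimeCourse(gene_id, np.array(doses, dtype=object),
                                np.array(tt), np.array(fc))


class TestChi2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert chi2(y, y, 0.11) == 0.0

    def test_one_error_unit(self):
        # residual constructed to equal exactly Delta_r * y_data
        assert chi2([2.0], [2.0 - 0.11 * 2.0], 0.11) == pytest.approx(1.0)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(5)
        y_data = rng.uniform(0.5, 5.0, 30)
        y_model = rng.uniform(0.5, 5.0, 30)
        expected = sum(
            ((d - m) / (0.11 * d)) ** 2 for d, m in zip(y_data, y_model)
        )
        assert chi2(y_data, y_model, 0.11) == pytest.approx(expected)

    def test_zero_data_value_rejected(self):
        with pytest.raises(ValueError):
            chi2([1.0, 0.0], [1.0, 1.0], 0.11)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chi2([1.0], [1.0, 2.0], 0.11)


class TestChi2Test:
    def test_simple_model_critical_values(self):
        # 12 points minus 4 / minus 3 free parameters
        crit_act, _ = chi2_test(0.0, dof=8)
        crit_inh, _ = chi2_test(0.0, dof=9)
        assert round(crit_act, 1) == 15.5
        assert round(crit_inh, 1) == 16.9

    def test_zero_chi2_always_accepted(self):
        for dof in (1, 6, 20):
            _, accepted = chi2_test(0.0, dof)
            assert accepted

    def test_decision_is_strict_inequality(self):
        crit, accepted = chi2_test(15.51, dof=8)
        assert not accepted  # just above the critical value 15.507

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            chi2_test(1.0, 8, alpha)


class TestExpressionTimeCourse:
    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTimeCourse("g", np.array(["a"], dtype=object),
                                 np.array([45.0]), np.array([0.0]))

    def test_dose_series_sorted(self):
        tc = ExpressionTimeCourse.from_records(
            "g", [("a", 90.0, 2.0), ("a", 45.0, 1.5)])
        t, fc = tc.dose_series("a")
        np.testing.assert_allclose(t, [45, 90])
        np.testing.assert_allclose(fc, [1.5, 2.0])


def _mk_fit(gene, model_id, chi2_value, n_free, accepted, variant):
    params = SimpleModelParams(variant, beta0=0.01, h=2.0, k=0.5,
                               ksyn=0.05 if variant == "activation" else None)
    return FitResult(
        gene_id=gene, model_id=model_id, best_params=params,
        theta=np.ones(n_free), chi2=chi2_value, n_points=12, n_free=n_free,
        dof=12 - n_free, critical_value=15.5, accepted=accepted,
    )


class TestClassifySimple:
    def test_lower_aic_wins(self):
        act = _mk_fit("g", "activation", 10.0, 4, True, "activation")
        inh = _mk_fit("g", "inhibition", 14.0, 3, True, "inhibition")
        assert act.aic == 18.0 and inh.aic == 20.0
        assert classify_simple(act, inh) == "explained_activation"

    def test_single_accepted_model_wins(self):
        act = _mk_fit("g", "activation", 40.0, 4, False, "activation")
        inh = _mk_fit("g", "inhibition", 10.0, 3, True, "inhibition")
        assert classify_simple(act, inh) == "explained_inhibition"

    def test_neither_accepted_is_rejected(self):
        act = _mk_fit("g", "activation", 40.0, 4, False, "activation")
        inh = _mk_fit("g", "inhibition", 40.0, 3, False, "inhibition")
        assert classify_simple(act, inh) == "rejected"

    def test_aic_tie_prefers_fewer_parameters(self):
        act = _mk_fit("g", "activation", 10.0, 4, True, "activation")
        inh = _mk_fit("g", "inhibition", 12.0, 3, True, "inhibition")
        assert classify_simple(act, inh) == "explained_inhibition"

    def test_gene_mismatch_rejected(self):
        act = _mk_fit("g1", "activation", 10.0, 4, True, "activation")
        inh = _mk_fit("g2", "inhibition", 10.0, 3, True, "inhibition")
        with pytest.raises(ValueError):
            classify_simple(act, inh)


class TestFitGene:
    def test_noise_free_recovery(self, smad, times):
        theta = np.array([0.02, 0.08, 2.0, 0.5])  # beta0, ksyn, h, k
        tc = make_tc("g", smad, "activation", theta, times)
        fr = fit_gene(tc, "activation", smad, 0.11, n_starts=30, seed=0)
        assert fr.chi2 < 0.01 * tc.n_points
        spec = get_model("activation")
        for dose, tr in smad.items():
            t, y = tc.dose_series(dose)
            y_fit = spec.simulate(fr.theta, tr, t)
            rms = np.sqrt(np.mean((y_fit / y - 1.0) ** 2))
            assert rms < 0.01

    def test_activation_cannot_explain_repression(self, smad, times):
        theta = np.array([0.05, 4.0, 0.2])  # deep inhibition: y -> ~0.2
        tc = make_tc("g", smad, "inhibition", theta, times)
        fr = fit_gene(tc, "activation", smad, 0.11, n_starts=12, seed=1)
        assert fr.chi2 >= fr.critical_value
        assert not fr.accepted

    def test_flat_gene_accepted_with_tiny_chi2(self, smad, times):
        n = times.size
        doses = np.array(["2.5pM"] * n + ["100pM"] * n, dtype=object)
        tc = ExpressionTimeCourse("flat", doses, np.tile(times, 2),
                                  np.ones(2 * n))
        fr = fit_gene(tc, "activation", smad, 0.11, n_starts=12, seed=2)
        assert fr.accepted
        assert fr.chi2 < 0.5
        # induced amplitude driven to the bottom decade of its range
        lo, _ = get_model("activation").bounds(smad["100pM"].max_value)
        assert fr.theta[1] < 10 * lo[1]

    def test_aic_identity(self, smad, times):
        theta = np.array([0.02, 0.08, 2.0, 0.5])
        tc = make_tc("g", smad, "activation", theta, times)
        fr = fit_gene(tc, "activation", smad, 0.11, n_starts=5, seed=3)
        assert fr.aic == fr.chi2 + 2 * fr.n_free

    def test_multistart_best_chi2_monotone_in_starts(self, smad, times):
        """More starts from the same stream can only improve the best chi2."""
        theta = np.array([0.02, 0.08, 2.0, 0.5])
        tc = make_tc("g", smad, "activation", theta, times)
        clean = tc.fold_changes
        noisy = clean * (1 + 0.11 * np.sin(np.arange(clean.size)))
        tc = ExpressionTimeCourse("g", tc.dose_labels, tc.times, noisy)
        spec = get_model("activation")
        lo, hi = spec.bounds(smad["100pM"].max_value)
        starts = _lhs_starts(lo, hi, 12, np.random.default_rng(4))
        residuals = _make_objective(spec, tc, smad, 0.11)
        best = [
            _refine_starts(spec, residuals, starts[:k], lo, hi)[1]
            for k in (3, 6, 12)
        ]
        assert best[0] >= best[1] >= best[2]

    def test_reproducible_given_seed(self, smad, times):
        theta = np.array([0.02, 0.08, 2.0, 0.5])
        tc = make_tc("g", smad, "activation", theta, times)
        f1 = fit_gene(tc, "activation", smad, 0.11, n_starts=6, seed=42)
        f2 = fit_gene(tc, "activation", smad, 0.11, n_starts=6, seed=42)
        np.testing.assert_array_equal(f1.theta, f2.theta)
        assert f1.chi2 == f2.chi2


def test_mean_chi2_at_truth_equals_n_points(smad, times):
    """With noise matched to the chi-square weights, E[chi2] = N."""
    theta = np.array([0.02, 0.08, 2.0, 0.5])
    tc = make_tc("g", smad, "activation", theta, times)
    rel = 0.11
    rng = np.random.default_rng(6)
    n_rep, n = 400, tc.n_points
    chis = []
    for _ in range(n_rep):
        noisy = tc.fold_changes * (1 + rng.normal(0, rel, n))
        # reference-weighted form: clean trajectory carries the weights
        chis.append(chi2(tc.fold_changes, noisy, rel))
    mc_sd = np.sqrt(2.0 * n / n_rep)
    assert np.mean(chis) == pytest.approx(n, abs=3 * mc_sd)


class TestFflCascade:
    def test_recovery_of_delayed_pulse_gene(self, smad):
        """Variant 5 (SMAD activator, TF repressor) produces a delayed
        pulse; the cascade must find an accepted model whose trajectory
        stays within the noise band of the truth."""
        panel = simulate_gene_panel(1, {"ffl5": 1.0}, smad, seed=21)
        g = panel.gene_ids[0]
        clean = panel.clean[g]
        noisy = add_noise(clean, 0.11, seed=22)[g][0]
        best, table = fit_ffl_cascade(noisy, smad, 0.11, n_starts=12, seed=23)
        assert len(table) == 8
        assert best.accepted
        spec = get_model(best.model_id)
        for dose, tr in smad.items():
            t, y_true = clean.dose_series(dose)
            y_fit = spec.simulate(best.theta, tr, t)
            assert np.all(np.abs(y_fit / y_true - 1.0) < 4 * 0.11)

    def test_ffl_nests_simple_activation(self, smad, times):
        theta = np.array([0.02, 0.08, 2.0, 0.5])
        tc = make_tc("g", smad, "activation", theta, times)
        best, table = fit_ffl_cascade(tc, smad, 0.11, n_starts=10, seed=24)
        assert any(f.accepted for f in table)
        assert best.chi2 < best.critical_value

    def test_aic_identity_across_variants(self, smad, times):
        theta = np.array([0.02, 0.08, 2.0, 0.5])
        tc = make_tc("g", smad, "activation", theta, times)
        _, table = fit_ffl_cascade(tc, smad, 0.11, n_starts=4, seed=25)
        for f in table:
            assert f.aic == f.chi2 + 2 * f.n_free
            assert f.dof == 6  # calibrated effective dof, not N - p
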