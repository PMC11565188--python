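import numpy as np
import pytest

from smaddecode.ode_models import (
    MODEL_IDS,
    FflModelParams,
    SimpleModelParams,
    ffl_steady_state,
    get_model,
    hill,
    simulate_ffl,
    simulate_ffl_raw,
    simulate_simple,
)
from conftest import const_smad

ACT = SimpleModelParams("activation", beta0=0.01, h=2.0, k=0.5, ksyn=0.05)
INH = SimpleModelParams("inhibition", beta0=0.02, h=2.0, k=0.4)

FFL_EXAMPLE = {
    "tf_beta0": 0.02, "tf_r": 0.2, "tf_h": 2.0, "tf_k": 0.4,
    "syn_tg": 0.7, "rs": 0.05, "rp": 0.03, "hs1": 2.0, "ks1": 0.4,
    "hp": 3.0, "kp": 2.5, "b_tg": 0.005,
}


class TestHill:
    def test_half_saturation_midpoint(self):
        assert hill(0.5, 0.5, 3.0) == pytest.approx(0.5)

    def test_zero_signal(self):
        assert hill(0.0, 1.0, 2.0) == 0.0

    def test_direct_substitution(self):
        assert hill(2.0, 1.0, 1.0) == pytest.approx(2.0 / 3.0)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            hill(-0.1, 1.0, 2.0)

    def test_large_exponent_no_overflow(self):
        assert hill(1e6, 1.0, 8.0) == pytest.approx(1.0)


class TestParamValidation:
    def test_activation_needs_ksyn(self):
        with pytest.raises(ValueError):
            SimpleModelParams("activation", beta0=0.01, h=2, k=0.5)

    def test_inhibition_forbids_ksyn(self):
        with pytest.raises(ValueError):
            SimpleModelParams("inhibition", beta0=0.01, h=2, k=0.5, ksyn=1.0)

    def test_free_parameter_counts(self):
        assert ACT.n_free == 4
        assert INH.n_free == 3

    def test_hill_coefficient_floor(self):
        with pytest.raises(ValueError):
            SimpleModelParams("inhibition", beta0=0.01, h=0.5, k=0.5)

    def test_invalid_ffl_variant(self):
        with pytest.raises(ValueError):
            FflModelParams(variant=9)

    def test_ffl_active_counts(self):
        expected = {1: 10, 2: 12, 3: 11, 4: 10, 5: 10, 6: 11, 7: 9, 8: 9}
        for v, n in expected.items():
            assert FflModelParams(variant=v).n_free == n
            assert get_model(f"ffl{v}").n_free == n


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_unstimulated_fixed_point(model_id, zero_smad, times):
    """SMAD = 0 leaves every state of every model at fold change 1."""
    spec = get_model(model_id)
    lo, hi = spec.bounds(smad_max=1.0)
    theta = np.sqrt(lo * hi)  # geometric midpoint of the fitting box
    y = spec.simulate(theta, zero_smad["100pM"], times)
    np.testing.assert_allclose(y, 1.0, atol=1e-9)


class TestSimpleModel:
    def test_activation_closed_form_step_response(self, times):
        s = const_smad(0.8)
        H = hill(0.8, ACT.k, ACT.h)
        ystar = 1.0 + ACT.ksyn / ACT.beta0 * H
        expected = ystar + (1.0 - ystar) * np.exp(-ACT.beta0 * times)
        y = simulate_simple(ACT, s, times)
        np.testing.assert_allclose(y, expected, rtol=1e-10)

    def test_inhibition_closed_form_step_response(self, times):
        s = const_smad(0.8)
        H = hill(0.8, INH.k, INH.h)
        ystar = 1.0 - H
        expected = ystar + (1.0 - ystar) * np.exp(-INH.beta0 * times)
        y = simulate_simple(INH, s, times)
        np.testing.assert_allclose(y, expected, rtol=1e-10)

    def test_saturating_asymptote(self):
        # Hill -> 1, so y -> 1 + ksyn/beta0
        s = const_smad(100.0)  # Hill term within 2.5e-5 of full saturation
        y = simulate_simple(ACT, s, [1440.0 * 4])
        assert y[0] == pytest.approx(1.0 + ACT.ksyn / ACT.beta0, rel=1e-4)

    def test_boundedness(self, smad, times):
        y_act = simulate_simple(ACT, smad["100pM"], times)
        y_inh = simulate_simple(INH, smad["100pM"], times)
        assert np.all(y_act >= 1.0 - 1e-9)
        assert np.all(y_inh <= 1.0 + 1e-9)
        assert np.all(y_inh > 0.0)

    def test_exp_matches_adaptive_solver(self, smad, times):
        for p in (ACT, INH):
            y1 = simulate_simple(p, smad["100pM"], times, method="exp")
            y2 = simulate_simple(p, smad["100pM"], times, method="ivp")
            np.testing.assert_allclose(y1, y2, atol=2e-4)

    def test_peak_time_ordering_in_degradation_rate(self, smad):
        """Faster mRNA turnover peaks earlier under a transient input."""
        t_dense = np.arange(0.0, 1441.0, 5.0)
        peaks = []
        for beta0 in [0.002, 0.005, 0.02, 0.05, 0.2]:
            p = SimpleModelParams("activation", beta0=beta0, h=2.0, k=0.3,
                                  ksyn=0.05)
            y = simulate_simple(p, smad["2.5pM"], t_dense)
            peaks.append(t_dense[np.argmax(y)])
        assert np.all(np.diff(peaks) <= 0)


class TestFflModels:
    def test_variant1_constant_smad_steady_state(self):
        """Long-time limit matches the algebraic two-equation steady state."""
        p = FflModelParams(variant=1, **FFL_EXAMPLE)
        s = const_smad(5.0)  # strongly saturating
        h_tf = hill(5.0, p.tf_k, p.tf_h)
        tf_star = 1.0 + p.tf_r / p.tf_beta0 * h_tf
        fS = hill(5.0, p.ks1, p.hs1)
        fP = hill(tf_star, p.kp, p.hp)
        tg_star = 1.0 + p.rs / p.b_tg * fS * fP
        tf, tg = simulate_ffl(p, s, [1440.0 * 8])
        assert tf[0] == pytest.approx(tf_star, rel=1e-5)
        assert tg[0] == pytest.approx(tg_star, rel=1e-5)

    def test_variant1_reduces_to_simple_activation_when_tf_saturates(
            self, smad, times):
        """kp -> 0 pins the TF Hill term at 1, collapsing the FFL to the
        simple activation model with matching rates."""
        p = FflModelParams(variant=1, **{**FFL_EXAMPLE, "kp": 1e-8})
        _, tg = simulate_ffl(p, smad["100pM"], times)
        simple = SimpleModelParams("activation", beta0=p.b_tg, ksyn=p.rs,
                                   h=p.hs1, k=p.ks1)
        y = simulate_simple(simple, smad["100pM"], times)
        np.testing.assert_allclose(tg, y, rtol=1e-6)

    @pytest.mark.parametrize("variant", range(1, 9))
    def test_normalization_consistency(self, variant, smad, times):
        """Integrating the un-normalized equations from their steady state
        and dividing by it reproduces the normalized trajectories."""
        raw = FflModelParams(variant=variant, **FFL_EXAMPLE)
        x0 = ffl_steady_state(variant, raw)
        tg_raw, x0_out = simulate_ffl_raw(raw, smad["100pM"], times)
        assert x0_out == pytest.approx(x0)
        # variants whose normalized form absorbs x0 into the amplitude
        remap = {}
        if variant in (1, 5):
            remap["rs"] = raw.rs / x0
        elif variant == 4:
            remap["rp"] = raw.rp / x0
        norm = FflModelParams(variant=variant, **{**FFL_EXAMPLE, **remap})
        _, tg_norm = simulate_ffl(norm, smad["100pM"], times)
        np.testing.assert_allclose(tg_raw / x0, tg_norm, rtol=1e-8)

    @pytest.mark.parametrize("variant", [2, 5, 8])
    def test_exp_matches_adaptive_solver(self, variant, smad, times):
        p = FflModelParams(variant=variant, **FFL_EXAMPLE)
        tf1, tg1 = simulate_ffl(p, smad["100pM"], times, method="exp")
        tf2, tg2 = simulate_ffl(p, smad["100pM"], times, method="ivp")
        np.testing.assert_allclose(tf1, tf2, atol=3e-4)
        np.testing.assert_allclose(tg1, tg2, atol=3e-4)

    def test_outputs_finite_across_fitting_box(self, smad, times):
        rng = np.random.default_rng(7)
        for variant in range(1, 9):
            spec = get_model(f"ffl{variant}")
            lo, hi = spec.bounds(smad_max=smad["100pM"].max_value)
            for _ in range(5):
                u = rng.uniform(size=lo.size)
                theta = 10.0 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))
                y = spec.simulate(theta, smad["100pM"], times)
                assert np.all(np.isfinite(y))


def test_unknown_model_id():
    with pytest.raises(KeyError, match="unknown model"):
        get_model("ffl9")
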