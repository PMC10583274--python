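"""Forward model assembly, complex least-squares fitting, phasing."""

import numpy as np
import pytest

import deerpol as dp
from deerpol.fitting import BackgroundModel, BiradicalModel


class TestForwardModel:
    def test_zero_mod_depth_reduces_to_background(self, t_grid):
        bi = dp.BiradicalFitModel(V0=0.8, k=1.2, t0=0.1, qB=2.0, epsilon=0.5,
                                  r0=3.7, w=0.2, qF=1.0, mod_depth=0.0)
        bg = dp.BackgroundFitModel(V0=0.8, k=1.2, t0=0.1, qB=2.0, epsilon=0.5)
        np.testing.assert_allclose(
            dp.forward_model(bi, t_grid), dp.forward_model(bg, t_grid),
            rtol=1e-12,
        )

    def test_unpolarized_model_is_real(self, t_grid):
        bi = dp.BiradicalFitModel(V0=1.0, k=0.7, t0=0.0, qB=3.0, epsilon=0.0,
                                  r0=4.0, w=0.3, qF=2.0, mod_depth=0.4)
        v = dp.forward_model(bi, t_grid)
        np.testing.assert_allclose(v.imag, 0.0, atol=1e-14)

    def test_round_trip_with_synthesizer(self, biradical_truth, t_grid):
        tr = dp.synthesize_trace(biradical_truth, t_grid, noise_sigma=0.0)
        np.testing.assert_array_equal(
            tr.V, dp.forward_model(biradical_truth, t_grid)
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dp.BackgroundFitModel(V0=-1.0)
        with pytest.raises(ValueError):
            dp.BiradicalFitModel(w=-0.1)


class TestBackgroundFit:
    def test_noiseless_self_consistency(self):
        truth = dp.BackgroundFitModel(V0=1.0, k=1.0, t0=0.0, qB=2.0,
                                      epsilon=0.07)
        t = np.linspace(-1, 5, 80)
        tr = dp.synthesize_trace(truth, t, 0.0)
        res = dp.fit_background(tr, 0.07)
        assert res.converged
        for name, true_val in [("V0", 1.0), ("k", 1.0), ("qB", 2.0)]:
            assert res.estimates[name] == pytest.approx(true_val, rel=1e-6)
        assert res.estimates["t0"] == pytest.approx(0.0, abs=1e-6)

    def test_unpolarized_qB_unidentifiable(self, t_grid):
        truth = dp.BackgroundFitModel(V0=1.0, k=1.0, t0=0.0, qB=1.0,
                                      epsilon=0.0)
        tr = dp.synthesize_trace(truth, t_grid, 0.0)
        res = dp.fit_background(tr, 0.0)
        assert "qB" in res.unidentifiable
        assert np.isinf(res.ci95["qB"])

    def test_degenerate_trace_rejected(self, t_grid):
        tr = dp.DeerTrace(t_grid, np.ones_like(t_grid), np.zeros_like(t_grid))
        with pytest.raises(ValueError):
            BackgroundModel(epsilon=0.5).fit(tr)

    def test_short_one_sided_trace_warns(self):
        truth = dp.BackgroundFitModel(V0=1.0, k=1.0, epsilon=0.5)
        t = np.linspace(0.1, 2.0, 6)
        tr = dp.synthesize_trace(truth, t, 0.0)
        with pytest.warns(UserWarning, match="qB"):
            dp.fit_background(tr, 0.5)

    def test_time_shift_invariance(self, background_truth):
        t = np.linspace(-1, 4, 80)
        tr = dp.synthesize_trace(background_truth, t, 0.0)
        shifted = dp.DeerTrace(t + 0.75, tr.re, tr.im)
        res = dp.fit_background(tr, background_truth.epsilon)
        res_s = dp.fit_background(shifted, background_truth.epsilon)
        assert res_s.estimates["t0"] - res.estimates["t0"] == pytest.approx(
            0.75, abs=1e-8
        )
        for name in ("V0", "k", "qB"):
            assert res_s.estimates[name] == pytest.approx(
                res.estimates[name], abs=1e-8
            )

    def test_residual_rms_matches_noise_level(self, background_truth, t_grid):
        sigma = 0.005
        tr = dp.synthesize_trace(background_truth, t_grid, sigma, seed=77)
        res = dp.fit_background(tr, background_truth.epsilon)
        assert res.residual_rms["re"] == pytest.approx(sigma, rel=0.10)
        assert res.residual_rms["im"] == pytest.approx(sigma, rel=0.10)

    @pytest.mark.parametrize("sigma", [0.02, 0.005, 0.001])
    def test_estimates_consistent_with_unbiasedness(self, background_truth,
                                                    t_grid, sigma):
        # the mean over replicates stays within 4 standard errors of truth
        # at every noise level, so any bias vanishes as σ -> 0
        n_rep = 30
        ests = {"k": [], "qB": []}
        for i in range(n_rep):
            tr = dp.synthesize_trace(background_truth, t_grid, sigma,
                                     seed=1000 + i)
            res = dp.fit_background(tr, background_truth.epsilon)
            ests["k"].append(res.estimates["k"])
            ests["qB"].append(res.estimates["qB"])
        for name, truth in [("k", background_truth.k),
                            ("qB", background_truth.qB)]:
            arr = np.array(ests[name])
            se = arr.std(ddof=1) / np.sqrt(n_rep)
            assert abs(arr.mean() - truth) <= 4 * se + 1e-9

    def test_sklearn_protocol(self, background_truth, t_grid):
        from sklearn.base import clone

        tr = dp.synthesize_trace(background_truth, t_grid, 0.0)
        est = BackgroundModel(epsilon=background_truth.epsilon)
        cloned = clone(est)
        cloned.fit(tr.t, tr.V)
        assert cloned.k_ == pytest.approx(background_truth.k, rel=1e-6)
        np.testing.assert_allclose(cloned.predict(t_grid), tr.V, atol=1e-8)
        assert est.get_params()["epsilon"] == background_truth.epsilon


class TestBiradicalFit:
    def test_noiseless_self_consistency(self, biradical_truth):
        t = np.linspace(-0.5, 5, 120)
        tr = dp.synthesize_trace(biradical_truth, t, 0.0)
        res = dp.fit_biradical(tr, biradical_truth.epsilon)
        assert res.converged
        assert res.estimates["r0"] == pytest.approx(3.7, abs=0.01)
        assert res.estimates["qF"] == pytest.approx(1.0, abs=0.01)
        for name in ("V0", "k", "qB", "w", "mod_depth"):
            assert res.estimates[name] == pytest.approx(
                getattr(biradical_truth, name), rel=1e-5, abs=1e-6
            )

    def test_no_modulation_flags_pair_parameters(self, t_grid):
        truth = dp.BiradicalFitModel(V0=1.0, k=1.0, t0=0.0, qB=2.0,
                                     epsilon=0.7, r0=3.7, w=0.2, qF=1.0,
                                     mod_depth=0.0)
        tr = dp.synthesize_trace(truth, t_grid, 0.0)
        res = dp.fit_biradical(tr, 0.7, init=truth)
        assert {"r0", "w", "qF"} <= set(res.unidentifiable)

    def test_short_trace_warns_about_r0(self):
        truth = dp.BiradicalFitModel(V0=1.0, k=0.5, epsilon=0.7, r0=5.0,
                                     w=0.3, mod_depth=0.3)
        t = np.linspace(-0.2, 0.6, 20)  # below one dipolar period at 5 nm
        tr = dp.synthesize_trace(truth, t, 0.0)
        with pytest.warns(UserWarning, match="period"):
            dp.fit_biradical(tr, 0.7, init=truth)

    def test_report_format(self, biradical_truth):
        t = np.linspace(-0.5, 5, 120)
        tr = dp.synthesize_trace(biradical_truth, t, 0.005, seed=4)
        res = dp.fit_biradical(tr, biradical_truth.epsilon)
        text = res.report()
        assert "r0" in text and "qF" in text and "residual_rms" in text
        d = res.as_dict()
        assert d["n_points"] == 120


class TestPhaseCorrect:
    # grid containing t = 0 exactly, so the phase reference sits at zero time
    t0_grid = np.linspace(-1.0, 4.0, 81)

    def test_already_phased_trace(self, background_truth):
        tr = dp.synthesize_trace(background_truth, self.t0_grid, 0.0)
        _, angle = dp.phase_correct(tr)
        assert angle == pytest.approx(0.0, abs=1e-12)

    def test_recovers_applied_rotation(self, background_truth):
        tr = dp.synthesize_trace(background_truth, self.t0_grid, 0.0)
        rot = tr.V * np.exp(1j * np.deg2rad(30.0))
        rotated = dp.DeerTrace(self.t0_grid, rot.real, rot.imag)
        corrected, angle = dp.phase_correct(rotated)
        assert angle == pytest.approx(-np.deg2rad(30.0), abs=1e-12)
        np.testing.assert_allclose(corrected.V, tr.V, atol=1e-12)

    def test_fit_invariant_under_rotation(self, background_truth):
        tr = dp.synthesize_trace(background_truth, self.t0_grid, 0.0)
        res_ref = dp.fit_background(tr, background_truth.epsilon)
        rot = tr.V * np.exp(1j * 1.234)
        corrected, _ = dp.phase_correct(
            dp.DeerTrace(self.t0_grid, rot.real, rot.imag)
        )
        res_rot = dp.fit_background(corrected, background_truth.epsilon)
        assert res_rot.estimates["qB"] == pytest.approx(
            res_ref.estimates["qB"], abs=1e-6
        )

    def test_zero_amplitude_reference_rejected(self):
        tr = dp.DeerTrace([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            dp.phase_correct(tr)
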