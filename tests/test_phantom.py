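"""Synthetic-phantom physics: input function, forward model, simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import waterpet as wp
from waterpet.phantom import LABEL_IDS, kappa_for_frame_cv, poisson_noisy_tac


class TestGammaVariateAif:
    def test_zero_at_and_before_appearance_time(self, aif):
        assert wp.gamma_variate_aif(aif, aif.t0_s) == 0.0
        assert wp.gamma_variate_aif(aif, aif.t0_s - 5.0) == 0.0
        assert wp.gamma_variate_aif(aif, -100.0) == 0.0

    def test_peak_location_is_t0_plus_alpha_beta(self):
        model = wp.AIFModel(recirc_fraction=0.0)
        t = np.linspace(0, 200, 200001)
        c = wp.gamma_variate_aif(model, t)
        t_peak = t[np.argmax(c)]
        assert t_peak == pytest.approx(model.t0_s + model.alpha * model.beta_s, abs=1e-2)

    def test_peak_normalization_alpha_one(self):
        model = wp.AIFModel(recirc_fraction=0.0, alpha=1.0)
        val = wp.gamma_variate_aif(model, model.t0_s + model.alpha * model.beta_s)
        assert val == pytest.approx(model.amplitude_kBq_mL, rel=1e-12)

    def test_nonnegative_and_bounded(self, aif):
        t = np.linspace(-10, 500, 5000)
        c = wp.gamma_variate_aif(aif, t)
        assert np.all(c >= 0)
        assert np.all(np.isfinite(c))
        assert c.max() <= aif.amplitude_kBq_mL * 1.0000001

    @pytest.mark.parametrize("bad", [{"alpha": 0.0}, {"beta_s": -1.0}, {"recirc_fraction": 1.0}])
    def test_invalid_shape_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            wp.AIFModel(**bad)


class TestForward1TCM:
    def test_zero_influx_gives_zero_tissue(self, aif, framing):
        ct = wp.forward_1tcm(0.0, 0.3, 0.0, aif, framing.mid_times_s)
        np.testing.assert_array_equal(ct, 0.0)

    def test_constant_input_closed_form(self):
        # C_T(t) = (K1 A / k2)(1 - exp(-k2 t)) for a constant input
        k1, k2, amp = 3.0, 0.3, 10.0
        t = np.linspace(1.0, 600.0, 40)
        ct = wp.forward_1tcm(k1, k2, 0.0, lambda tt: np.full_like(np.asarray(tt, float), amp), t)
        k1_ps, k2_ps = k1 / 6000.0, k2 / 60.0
        expected = (k1_ps * amp / k2_ps) * (1.0 - np.exp(-k2_ps * t))
        np.testing.assert_allclose(ct, expected, rtol=1e-6)
        # saturation level
        ct_inf = wp.forward_1tcm(k1, k2, 0.0, lambda tt: np.full_like(np.asarray(tt, float), amp),
                                 np.array([30000.0]))
        assert ct_inf[0] == pytest.approx(k1_ps * amp / k2_ps, rel=1e-6)

    def test_matches_fine_step_ode_oracle(self, aif, framing):
        k1, k2, delay = 3.0, 0.3, 5.0

        def rhs(t, y):
            return [k1 / 6000.0 * wp.gamma_variate_aif(aif, t - delay) - k2 / 60.0 * y[0]]

        sol = solve_ivp(rhs, [0, framing.total_duration_s], [0.0],
                        t_eval=framing.mid_times_s, max_step=0.01, rtol=1e-10, atol=1e-14)
        ct = wp.forward_1tcm(k1, k2, delay, aif, framing.mid_times_s)
        rel = np.abs(ct - sol.y[0]) / np.maximum(np.abs(sol.y[0]), 1e-12)
        assert rel.max() < 1e-3

    def test_linear_in_k1(self, aif, framing):
        c1 = wp.forward_1tcm(2.0, 0.3, 3.0, aif, framing.mid_times_s)
        c2 = wp.forward_1tcm(4.0, 0.3, 3.0, aif, framing.mid_times_s)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)


class TestSimulateDynamicScan:
    def test_noiseless_voxels_equal_forward_model_exactly(self, small_phantom, aif):
        dyn, truth = wp.simulate_dynamic_scan(
            phantom=small_phantom, aif=aif, noise=wp.NoiseModel(kappa=0.0), apply_decay=False
        )
        for name in ("posterior", "anterior", "artery"):
            vox = dyn.data[truth.labels == LABEL_IDS[name]]
            np.testing.assert_array_equal(vox, np.broadcast_to(truth.tac_ideal[name], vox.shape))
        assert np.all(dyn.data[truth.labels == 0] == 0.0)

    def test_fixed_seed_reproduces_bit_identical_scan(self, small_phantom, aif):
        kw = dict(phantom=small_phantom, aif=aif, noise=wp.NoiseModel(kappa=5.0, seed=7))
        dyn1, _ = wp.simulate_dynamic_scan(**kw)
        dyn2, _ = wp.simulate_dynamic_scan(**kw)
        np.testing.assert_array_equal(dyn1.data, dyn2.data)

    def test_high_count_scale_approaches_noiseless_mean(self, small_phantom, aif):
        # law of large numbers over the posterior compartment
        dyn, truth = wp.simulate_dynamic_scan(
            phantom=small_phantom, aif=aif, noise=wp.NoiseModel(kappa=1e4, seed=1)
        )
        mask = truth.labels == LABEL_IDS["posterior"]
        mean_tac = dyn.data[mask].mean(axis=0)
        expected = truth.tac_image["posterior"]
        pos = expected > 0.01 * expected.max()
        rel = np.abs(mean_tac[pos] - expected[pos]) / expected[pos]
        assert rel.max() < 0.01

    def test_doubling_k1_doubles_noiseless_tissue_curve(self, small_phantom, aif):
        out = {}
        for k1 in (2.0, 4.0):
            kin = {"posterior": wp.TissueKinetics(k1=k1, k2_per_min=0.3, delay_s=3.0)}
            _, truth = wp.simulate_dynamic_scan(
                phantom=small_phantom, aif=aif, kinetics=kin,
                noise=wp.NoiseModel(kappa=0.0), apply_decay=False,
            )
            out[k1] = truth.tac_ideal["posterior"]
        np.testing.assert_allclose(out[4.0], 2.0 * out[2.0], rtol=1e-12)

    def test_late_washout_decays_at_rate_k2(self, small_phantom):
        # once the input has returned to ~0 the tissue curve is a pure
        # exponential with rate k2: check the log-linear slope on late frames
        sharp = wp.AIFModel(t0_s=5.0, alpha=2.0, beta_s=2.0, recirc_fraction=0.0)
        k2 = 0.6
        kin = {"posterior": wp.TissueKinetics(k1=3.0, k2_per_min=k2, delay_s=0.0)}
        _, truth = wp.simulate_dynamic_scan(
            phantom=small_phantom, aif=sharp, kinetics=kin,
            noise=wp.NoiseModel(kappa=0.0), apply_decay=False,
        )
        fs = truth.framing
        # equal-duration late frames only, so the frame-average factor cancels
        late = (fs.mid_times_s > 200.0) & (fs.mid_times_s < 330.0)
        slope = np.polyfit(fs.mid_times_s[late], np.log(truth.tac_ideal["posterior"][late]), 1)[0]
        assert slope * 60.0 == pytest.approx(-k2, rel=0.01)

    def test_unknown_kinetics_label_rejected(self, small_phantom, aif):
        with pytest.raises(ValueError, match="absent"):
            wp.simulate_dynamic_scan(
                phantom=small_phantom, aif=aif,
                kinetics={"liver": wp.TissueKinetics(k1=3.0, k2_per_min=0.3)},
            )

    def test_overlapping_structures_rejected(self):
        cfg = wp.LegPhantomConfig(
            shape=(32, 32, 8),
            cylinders={
                "tibia": wp.Cylinder((0.0, 0.0), 8.0),
                "artery": wp.Cylinder((2.0, 0.0), 3.0),
            },
            knee_z_mm=12.0,
        )
        with pytest.raises(ValueError, match="overlaps"):
            cfg.build_labels()


class TestTacLevelNoise:
    def test_kappa_calibration_hits_target_cv(self, framing):
        values = np.linspace(0.1, 20.0, framing.n_frames)
        kappa = kappa_for_frame_cv(0.05, values, framing, volume_mL=3.5)
        j = np.argmax(values)
        lam = kappa * values[j] * framing.durations_s[j] * 3.5
        assert 1.0 / np.sqrt(lam) == pytest.approx(0.05, rel=1e-12)

    def test_noisy_tac_is_unbiased(self, framing):
        values = np.full(framing.n_frames, 10.0)
        rng = np.random.default_rng(3)
        draws = np.array([
            poisson_noisy_tac(values, framing, 5.0, 3.5, rng) for _ in range(4000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), values, rtol=0.02)
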