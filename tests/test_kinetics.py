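"""One-tissue-compartment fitting and its numerical core."""

import numpy as np
import pytest

import waterpet as wp
from waterpet.kinetics import _exp_conv_uniform, _frame_average_from_fine
from waterpet.phantom import kappa_for_frame_cv, poisson_noisy_tac
from waterpet.tac import TimeActivityCurve

from conftest import make_noiseless_curves


class TestConvolveExp:
    def test_boxcar_matches_closed_form(self):
        # boxcar height h on [0, T]: rise (h/k)(1-exp(-k t)), then decay
        height, T, k2 = 5.0, 60.0, 0.6
        k = k2 / 60.0
        fs = wp.build_framing([(120, 5)])  # 600 s of 5-s frames

        def closed_form(t):
            t = np.asarray(t, float)
            rise = (height / k) * (1.0 - np.exp(-k * np.minimum(t, T)))
            return np.where(t <= T, rise, rise * np.exp(-k * (t - T)))

        boxcar = TimeActivityCurve(
            fs.mid_times_s, fs.durations_s,
            np.where(fs.mid_times_s <= T, height, 0.0), role="input",
        )
        # evaluate on a fine grid directly; the step at T is represented as
        # a one-step ramp, so compare the rise and the decay separately
        h = 0.01
        t_fine = np.arange(int(600 / h) + 1) * h
        fine_vals = np.where(t_fine <= T, height, 0.0)
        got = _exp_conv_uniform(fine_vals, k, h)
        scale = closed_form(t_fine).max()
        rise = t_fine <= T
        assert np.abs(got[rise] - closed_form(t_fine[rise])).max() / scale < 1e-6
        # beyond the ramp the input is zero: pure exponential decay
        i1 = int(round((T + h) / h))
        decay = got[i1] * np.exp(-k * (t_fine[i1:] - t_fine[i1]))
        assert np.abs(got[i1:] - decay).max() / scale < 1e-6
        # and the public frame-averaged route agrees with averaged closed form
        frames = wp.convolve_exp(boxcar, k2, fine_step_s=h, framing=fs)
        assert frames.shape == (fs.n_frames,)

    def test_k2_to_zero_limit_is_running_integral(self):
        fs = wp.build_framing([(20, 5)])
        rng = np.random.default_rng(0)
        vals = rng.random(fs.n_frames) * 10
        curve = TimeActivityCurve(fs.mid_times_s, fs.durations_s, vals, role="input")
        out = wp.convolve_exp(curve, 1e-9)
        # frame-averaged running integral of the interpolated input
        h = 0.05
        t_fine = np.arange(int(100 / h) + 1) * h
        fine = np.interp(t_fine, np.r_[0.0, fs.mid_times_s], np.r_[0.0, vals])
        integral = np.concatenate([[0.0], np.cumsum((fine[1:] + fine[:-1]) * h / 2)])
        expected = _frame_average_from_fine(integral, h, fs)
        np.testing.assert_allclose(out, expected, rtol=1e-4)

    def test_halving_fine_step_converged(self, framing, aif):
        idif, _ = make_noiseless_curves(3.0, 0.3, 0.0, aif, framing)
        a = wp.convolve_exp(idif, 0.3, fine_step_s=0.05, framing=framing)
        b = wp.convolve_exp(idif, 0.3, fine_step_s=0.025, framing=framing)
        assert np.abs(a - b).max() / np.abs(b).max() < 1e-6

    def test_invalid_step_rejected(self, framing, aif):
        idif, _ = make_noiseless_curves(3.0, 0.3, 0.0, aif, framing)
        with pytest.raises(ValueError):
            wp.convolve_exp(idif, 0.3, fine_step_s=0.0)


class TestConvertK1Units:
    @pytest.mark.parametrize("raw,expected", [(0.0375, 3.75), (0.0, 0.0), (0.01, 1.0)])
    def test_display_scale(self, raw, expected):
        assert wp.convert_k1_units(raw) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            wp.convert_k1_units(-0.1)


class TestFit1TCM:
    def test_recovers_known_parameters_noiseless(self, framing, aif):
        k1, k2, delay = 3.0, 0.3, 5.0
        idif, tissue = make_noiseless_curves(k1, k2, delay, aif, framing)
        res = wp.fit_1tcm(tissue, idif)
        assert abs(res.k1 - k1) / k1 < 0.02
        assert abs(res.delay_s - delay) <= 0.5
        assert abs(res.k2_per_min - k2) / k2 < 0.05

    def test_recovery_grid_spanning_observed_perfusion_range(self, framing, aif):
        # K1 grid bracketing the 1.54-5.22 mL/100cm^3/min range seen in
        # patient calves, crossed with three washout rates
        worst = 0.0
        for k1 in (1.5, 2.5, 3.5, 4.5, 5.2):
            for k2 in (0.2, 0.4, 0.6):
                idif, tissue = make_noiseless_curves(k1, k2, 5.0, aif, framing)
                res = wp.fit_1tcm(tissue, idif)
                worst = max(worst, abs(res.k1 - k1) / k1)
                assert abs(res.delay_s - 5.0) <= 0.5
        assert worst < 0.02

    def test_zero_tissue_curve_gives_zero_k1_and_wrss(self, framing, aif):
        idif, _ = make_noiseless_curves(3.0, 0.3, 0.0, aif, framing)
        zero = TimeActivityCurve(framing.mid_times_s, framing.durations_s,
                                 np.zeros(framing.n_frames))
        res = wp.fit_1tcm(zero, idif)
        assert res.k1 == 0.0
        assert res.wrss == 0.0

    def test_all_zero_input_rejected(self, framing):
        zero = TimeActivityCurve(framing.mid_times_s, framing.durations_s,
                                 np.zeros(framing.n_frames))
        tissue = TimeActivityCurve(framing.mid_times_s, framing.durations_s,
                                   np.ones(framing.n_frames))
        with pytest.raises(ValueError, match="degenerate input"):
            wp.fit_1tcm(tissue, TimeActivityCurve(
                framing.mid_times_s, framing.durations_s,
                np.zeros(framing.n_frames), role="input"))

    def test_mismatched_framings_rejected(self, framing, aif):
        idif, tissue = make_noiseless_curves(3.0, 0.3, 0.0, aif, framing)
        other = wp.build_framing([(10, 37)])
        shifted = TimeActivityCurve(other.mid_times_s, other.durations_s,
                                    np.ones(other.n_frames))
        with pytest.raises(ValueError, match="framing"):
            wp.fit_1tcm(shifted, idif)

    def test_invariant_to_common_rescaling_of_concentration_units(self, framing, aif):
        idif, tissue = make_noiseless_curves(3.0, 0.3, 5.0, aif, framing)
        res1 = wp.fit_1tcm(tissue, idif)
        scale = 37.0  # e.g. kBq/mL -> nCi/mL
        idif2 = TimeActivityCurve(idif.mid_times_s, idif.durations_s,
                                  scale * idif.values, role="input")
        tissue2 = TimeActivityCurve(tissue.mid_times_s, tissue.durations_s,
                                    scale * tissue.values)
        res2 = wp.fit_1tcm(tissue2, idif2)
        assert res2.k1 == pytest.approx(res1.k1, rel=1e-6)
        assert res2.delay_s == res1.delay_s

    def test_returned_wrss_not_beaten_by_any_grid_candidate(self, framing, aif):
        # bookkeeping: re-evaluate every grid candidate explicitly
        cfg = wp.FitConfig(n_k2=16, polish=False)
        rng = np.random.default_rng(1)
        idif, tissue = make_noiseless_curves(3.0, 0.3, 5.0, aif, framing)
        noisy = TimeActivityCurve(
            tissue.mid_times_s, tissue.durations_s,
            tissue.values * (1 + 0.05 * rng.standard_normal(framing.n_frames)),
        )
        res = wp.fit_1tcm(noisy, idif, cfg)
        w = framing.durations_s / framing.durations_s.sum()
        from waterpet.kinetics import _input_on_fine_grid

        _, fine = _input_on_fine_grid(idif, framing.total_duration_s, 0.05)
        for k2 in cfg.k2_grid_per_min:
            y = _exp_conv_uniform(fine, k2 / 60.0, 0.05)
            for delay in cfg.delay_grid_s:
                b = _frame_average_from_fine(y, 0.05, framing, shift_s=delay)
                denom = np.sum(w * b * b)
                k1c = max(0.0, np.sum(w * b * noisy.values) / denom) if denom > 0 else 0.0
                wrss = np.sum(w * (noisy.values - k1c * b) ** 2)
                assert res.wrss <= wrss + 1e-12

    def test_noisy_recovery_rmse_under_ten_percent(self, framing, aif):
        # frame CV ~5% on the tissue TAC, 50 replicates
        k1, k2, delay = 3.0, 0.3, 5.0
        idif, tissue = make_noiseless_curves(k1, k2, delay, aif, framing)
        vol = 3.534  # dual-sphere VOI volume in mL
        kappa = kappa_for_frame_cv(0.05, tissue.values, framing, vol)
        rng = np.random.default_rng(1234)
        errs = []
        for _ in range(50):
            noisy = poisson_noisy_tac(tissue.values, framing, kappa, vol, rng)
            res = wp.fit_1tcm(TimeActivityCurve(
                framing.mid_times_s, framing.durations_s, noisy), idif)
            errs.append((res.k1 - k1) / k1)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.10
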