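"""Imaging-response tests: neuropil correction, ΔF/F arithmetic, response
amplitudes against a trapezoidal oracle, the two-criterion significance
test, ROC threshold calibration, CI/LI behavior, and tuning metrics."""

import numpy as np
import pandas as pd
import pytest

from cohear import imaging


def _session(f_cell, f_bg, onset_frames=(50,), frame_rate=30.0):
    n = f_cell.shape[1]
    trials = pd.DataFrame(
        {"stim_id": ["s"] * len(onset_frames), "onset_frame": list(onset_frames)}
    )
    return imaging.RoiSession(
        f_cell=f_cell,
        f_bg=f_bg,
        coords=np.zeros((f_cell.shape[0], 2)),
        frame_rate=frame_rate,
        trials=trials,
    )


class TestNeuropilCorrect:
    def test_zero_background_is_identity(self):
        f_cell = np.random.default_rng(0).uniform(50, 150, (3, 200))
        sess = _session(f_cell, np.zeros_like(f_cell))
        f, include = imaging.neuropil_correct(sess)
        assert np.array_equal(f, f_cell)
        assert include.all()

    def test_equal_brightness_excluded(self):
        # F_cell = F_bg = 100: corrected F = 10, and not 3% brighter
        f = np.full((1, 100), 100.0)
        sess = _session(f, f.copy())
        corrected, include = imaging.neuropil_correct(sess, r=0.9)
        assert np.allclose(corrected, 10.0)
        assert not include[0]

    def test_r_zero_is_no_correction(self):
        rng = np.random.default_rng(1)
        f_cell, f_bg = rng.uniform(80, 120, (2, 2, 150))
        sess = _session(f_cell, f_bg)
        f, _ = imaging.neuropil_correct(sess, r=0.0)
        assert np.array_equal(f, f_cell)

    def test_brightness_rule_boundary(self):
        f_cell = np.full((2, 100), 103.0)
        f_bg = np.full((2, 100), 100.0)
        f_cell[1] = 102.9
        _, include = imaging.neuropil_correct(_session(f_cell, f_bg))
        assert include[0] and not include[1]


class TestTrialDff:
    def test_constant_trace_gives_zero(self):
        f = np.full(300, 90.0)
        dff = imaging.trial_dff(f, np.array([100]), 30.0)
        assert np.allclose(dff, 0.0)

    def test_offset_arithmetic(self):
        # F0 = 80, offset 20, response F = 150 -> ΔF/F = 0.7
        f = np.full(300, 80.0)
        f[100:160] = 150.0
        dff = imaging.trial_dff(f, np.array([100]), 30.0, offset=20.0)
        assert np.allclose(dff[0, 30:60], 0.7)

    def test_scale_invariance_at_zero_offset(self):
        rng = np.random.default_rng(2)
        f = 100 + np.abs(rng.normal(0, 10, 400))
        a = imaging.trial_dff(f, np.array([200]), 30.0, offset=0.0)
        b = imaging.trial_dff(2 * f, np.array([200]), 30.0, offset=0.0)
        assert np.allclose(a, b)

    def test_window_bounds_checked(self):
        with pytest.raises(ValueError):
            imaging.trial_dff(np.zeros(100), np.array([10]), 30.0)


class TestResponseAmplitude:
    def test_zero_trace(self):
        per, mean = imaging.response_amplitude(np.zeros((5, 120)), 30.0, baseline_frames=30)
        assert mean == 0.0 and np.array_equal(per, np.zeros(5))

    def test_rectangular_pulse_area(self):
        # 0.5 ΔF/F for 0.6 s inside a 1 s window -> ~0.3 ΔF/F·s
        fr = 30.0
        dff = np.zeros((1, 120))
        dff[0, 30:48] = 0.5
        _, auc = imaging.response_amplitude(dff, fr, baseline_frames=30)
        assert abs(auc - 0.3) <= 0.5 / fr  # trapezoid edge within one frame

    def test_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(3)
        fr = 30.0
        dff = rng.normal(0, 0.3, (4, 150))
        per, _ = imaging.response_amplitude(dff, fr, baseline_frames=30)
        dt = 1.0 / fr
        for i in range(4):
            seg = dff[i, 30:60]
            oracle = sum((seg[k] + seg[k + 1]) / 2 * dt for k in range(seg.size - 1))
            assert abs(per[i] - oracle) < 1e-9

    def test_charge_mode_integrates_negative_part(self):
        fr = 10.0
        trace = np.zeros((1, 40))
        trace[0, 10:20] = -2.0  # inward current
        per, _ = imaging.response_amplitude(
            trace, fr, window_s=1.0, baseline_frames=10, mode="charge"
        )
        assert per[0] > 0
        with pytest.raises(ValueError):
            imaging.response_amplitude(trace, fr, window_s=10.0, baseline_frames=10)


class TestSignificance:
    fr = 30.0
    n_base = 30

    def _trials(self, plateau_trials, n_trials=5, plateau=1.0, dur_frames=18, seed=0):
        rng = np.random.default_rng(seed)
        dff = rng.normal(0, 0.02, (n_trials, 120))
        for t in plateau_trials:
            dff[t, self.n_base : self.n_base + dur_frames] += plateau
        return dff

    def test_noise_only_not_significant(self):
        sig, _ = imaging.test_significance(
            self._trials([]), self.fr, 3.3, baseline_frames=self.n_base
        )
        assert not sig

    def test_plateau_in_most_trials_significant(self):
        # suprathreshold 0.6 s plateau in 4/5 trials and hence in the mean
        sig, diag = imaging.test_significance(
            self._trials([0, 1, 2, 3]), self.fr, 3.3, baseline_frames=self.n_base
        )
        assert sig and diag["single_trial_criterion"] and diag["mean_trace_criterion"]

    def test_mean_only_fails_single_trial_criterion(self):
        # large plateau in 2/5 trials: the mean crosses but criterion 1 fails
        dff = self._trials([0, 1], plateau=3.0)
        sig, diag = imaging.test_significance(dff, self.fr, 3.3, baseline_frames=self.n_base)
        assert not sig
        assert diag["mean_trace_criterion"] and not diag["single_trial_criterion"]

    def test_short_plateau_fails_duration(self):
        dff = self._trials([0, 1, 2, 3, 4], dur_frames=10)  # 0.33 s < 0.5 s
        sig, _ = imaging.test_significance(dff, self.fr, 3.3, baseline_frames=self.n_base)
        assert not sig

    @pytest.mark.parametrize("k_lo, k_hi", [(1.6, 2.6), (2.6, 3.3), (3.3, 8.0)])
    def test_monotone_in_threshold(self, k_lo, k_hi):
        dff = self._trials([0, 1, 2], plateau=0.12, seed=4)
        lo, _ = imaging.test_significance(dff, self.fr, k_lo, baseline_frames=self.n_base)
        hi, _ = imaging.test_significance(dff, self.fr, k_hi, baseline_frames=self.n_base)
        assert lo or not hi  # raising k never flips non-significant -> significant

    def test_zero_baseline_sd_raises(self):
        with pytest.raises(imaging.NoBaselineVarianceError):
            imaging.test_significance(
                np.zeros((3, 120)), self.fr, 3.3, baseline_frames=self.n_base
            )


class TestCalibrateThreshold:
    def test_separated_classes_gap_midpoint(self):
        scores = np.array([0.0, 0.5, 1.0, 3.0, 3.5, 4.0])
        labels = np.array([False, False, False, True, True, True])
        thr, diag = imaging.calibrate_threshold(scores, labels)
        assert thr == pytest.approx(2.0)
        assert diag["tpr"] == 1.0 and diag["fpr"] == 0.0

    def test_shuffled_labels_near_tenth_percentile(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 4000)
        labels = rng.random(4000) < 0.5
        thr, diag = imaging.calibrate_threshold(scores, labels)
        assert abs(thr - np.quantile(scores[labels], 0.10)) < 0.1
        assert diag["tpr"] >= 0.90

    def test_gaussian_classes_closed_form(self):
        rng = np.random.default_rng(6)
        neg = rng.normal(0, 1, 20_000)
        pos = rng.normal(3, 1, 20_000)
        scores = np.concatenate([neg, pos])
        labels = np.concatenate([np.zeros(neg.size, bool), np.ones(pos.size, bool)])
        thr, _ = imaging.calibrate_threshold(scores, labels)
        assert abs(thr - (3.0 - 1.2816)) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            imaging.calibrate_threshold(np.arange(5.0), np.ones(5, bool))


class TestIndices:
    def test_ci_boundary_and_symmetry(self):
        assert imaging.coincidence_index(0.4, 0.4) == 0.0
        assert imaging.coincidence_index(0.4, 0.0) == 1.0
        assert imaging.coincidence_index(0.0, 0.4) == -1.0

    def test_ci_clips_negative_shifted_response(self):
        assert imaging.coincidence_index(0.3, -0.1) == 1.0

    def test_ci_undefined_sentinel(self):
        assert np.isnan(imaging.coincidence_index(0.0, -0.2))

    @pytest.mark.parametrize("scale", [0.1, 3.0, 100.0])
    def test_ci_li_scale_invariance(self, scale):
        assert imaging.coincidence_index(0.3, 0.1) == pytest.approx(
            imaging.coincidence_index(0.3 * scale, 0.1 * scale)
        )
        assert imaging.linearity_index(0.9, 0.45) == pytest.approx(
            imaging.linearity_index(0.9 * scale, 0.45 * scale)
        )

    def test_ci_antisymmetry(self):
        assert imaging.coincidence_index(0.7, 0.2) == -imaging.coincidence_index(0.2, 0.7)

    def test_li_examples(self):
        assert imaging.linearity_index(0.45, 0.45) == 0.0
        assert imaging.linearity_index(0.0, 0.3) == -1.0
        # components {0.1, 0.2, 0.15} sum to 0.45 against H = 0.9
        assert imaging.linearity_index(0.9, 0.1 + 0.2 + 0.15) == pytest.approx(1 / 3)

    def test_li_whole_cell_shift_average(self):
        li = {-30.0: 0.2, -15.0: 0.4, 15.0: 0.0, 30.0: -0.2, -45.0: 0.9}
        assert imaging.average_li_over_shifts(li) == pytest.approx(0.1)

    def test_ci_pooling_excludes_45ms_and_sentinels(self):
        df = pd.DataFrame(
            {
                "delta_onset": [-45.0, -30.0, -15.0, 15.0, 30.0, 45.0],
                "ci": [0.9, 0.5, np.nan, 0.1, 0.3, 0.8],
            }
        )
        pooled = imaging.pool_ci(df)
        assert sorted(pooled) == [0.1, 0.3, 0.5]


class TestTuningMetrics:
    freqs = np.geomspace(4000, 64000, 17)
    levels = np.array([30.0, 50.0, 70.0])

    def test_single_responsive_cell_cf(self):
        amps = np.zeros((3, 17))
        sig = np.zeros((3, 17), bool)
        amps[0, 8] = 1.0
        sig[0, 8] = True
        tm = imaging.tuning_metrics(amps, sig, self.freqs, self.levels)
        # threshold at the lowest tested level -> CF averages the two estimates,
        # which coincide for a lone peak
        assert tm.threshold_level_db == 30.0
        assert abs(np.log2(tm.cf_hz / self.freqs[8])) < 0.3

    def test_responsive_only_at_70db(self):
        amps = np.zeros((3, 17))
        sig = np.zeros((3, 17), bool)
        amps[2, 5] = 1.0
        sig[2, 5] = True
        tm = imaging.tuning_metrics(amps, sig, self.freqs, self.levels)
        assert tm.threshold_level_db == 70.0
        assert tm.cf_hz == pytest.approx(self.freqs[5])

    def test_bw70_recovers_planted_gaussian_width(self):
        log_f = np.log2(self.freqs)
        mu, sigma = np.log2(16000), 0.8
        amps = np.tile(np.exp(-((log_f - mu) ** 2) / (2 * sigma**2)), (3, 1))
        half_max_width = 2 * sigma * np.sqrt(2 * np.log(2))
        sig = amps > 0.5  # significance exactly at half max
        tm = imaging.tuning_metrics(amps, sig, self.freqs, self.levels)
        assert abs(tm.bw70_octaves - half_max_width) / half_max_width < 0.10

    def test_no_significant_response_is_none(self):
        assert (
            imaging.tuning_metrics(
                np.zeros((3, 17)), np.zeros((3, 17), bool), self.freqs, self.levels
            )
            is None
        )
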