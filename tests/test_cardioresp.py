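"""Physiological preprocessing, event detection and rate analyses."""

import numpy as np
import pytest

from arrestlab import cardioresp as cr
from arrestlab import synthio


class TestPreprocess:
    def test_constant_trace_becomes_zeros(self):
        out = cr.preprocess_trace(np.full(1000, 3.7), "flow")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_output_is_zero_mean(self):
        rng = np.random.default_rng(0)
        out = cr.preprocess_trace(rng.normal(2.0, 1.0, 5000), "ecg")
        assert abs(out.mean()) < 1e-9

    def test_impulse_smeared_to_window_plateau(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        out = cr.preprocess_trace(x, "flow")  # 21-sample window at 1 kHz
        plateau = out[990:1011]
        np.testing.assert_allclose(plateau, plateau[0], atol=1e-12)
        # plateau height above the (offset-removed) floor is 1/window
        assert plateau[0] - out[0] == pytest.approx(1.0 / 21.0, abs=1e-9)

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            cr.preprocess_trace(np.zeros(10), "flow")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            cr.preprocess_trace(np.zeros(100), "emg")


class TestDetectEvents:
    def test_flat_trace_yields_empty_series(self):
        ev = cr.detect_events(np.zeros(5000), "breath")
        assert len(ev) == 0

    def test_counts_and_times_match_generator_truth(self, apnea_session):
        rec, truth = apnea_session
        cleaned = cr.preprocess_trace(rec.flow, "flow", rec.sample_rate)
        breaths = cr.detect_events(cleaned, "breath", rec.sample_rate)
        assert len(breaths) == len(truth.breath_times)
        assert np.max(np.abs(breaths.times - truth.breath_times)) < 0.002
        cleaned = cr.preprocess_trace(rec.ecg, "ecg", rec.sample_rate)
        beats = cr.detect_events(cleaned, "beat", rec.sample_rate)
        assert len(beats) == len(truth.beat_times)
        assert np.max(np.abs(beats.times - truth.beat_times)) < 0.002

    def test_amplitude_scaling_leaves_event_times_unchanged(self, apnea_session):
        rec, _ = apnea_session
        cleaned = cr.preprocess_trace(rec.flow, "flow", rec.sample_rate)
        e1 = cr.detect_events(cleaned, "breath", rec.sample_rate)
        e2 = cr.detect_events(2.0 * cleaned, "breath", rec.sample_rate)
        np.testing.assert_array_equal(e1.times, e2.times)

    def test_noise_robust_recall_and_precision(self):
        cfg = synthio.PhysioSimConfig(
            session_duration=60.0, resp_effect="none", noise_sd=0.1,
            resp_jitter=0.03, heart_jitter=0.02, seed=7)
        rec, truth = synthio.gen_physio_session(cfg)
        for name, kind, true_t in (("flow", "breath", truth.breath_times),
                                   ("ecg", "beat", truth.beat_times)):
            cleaned = cr.preprocess_trace(getattr(rec, name), name,
                                          rec.sample_rate)
            ev = cr.detect_events(cleaned, kind, rec.sample_rate)
            tol = 0.03
            tp = sum(np.min(np.abs(true_t - e)) < tol for e in ev.times)
            assert tp / len(ev) >= 0.99      # precision
            recall = sum(np.min(np.abs(ev.times - t0)) < tol
                         for t0 in true_t) / len(true_t)
            assert recall >= 0.99


class TestPSTH:
    def test_hand_binned_pair_of_events(self):
        # one trial, events at -0.05 and +0.05 s: one count in each of the
        # two bins adjacent to onset -> 10 Hz each
        psth = cr.build_psth([np.array([-0.05, 0.05])], stim_duration=1.0)
        k_pre = np.flatnonzero(np.isclose(psth.centers, -0.05))[0]
        k_post = np.flatnonzero(np.isclose(psth.centers, 0.05))[0]
        assert psth.rate[k_pre] == pytest.approx(10.0)
        assert psth.rate[k_post] == pytest.approx(10.0)
        assert psth.counts.sum() == 2

    def test_no_events_gives_all_zero(self):
        psth = cr.build_psth([np.array([])], stim_duration=1.0)
        assert np.all(psth.rate == 0.0)

    def test_event_count_conserved_through_binning(self, apnea_session):
        from arrestlab import EventSeries
        rec, truth = apnea_session
        onsets = np.array([w[0] for w in rec.stim_windows()])
        trials = cr.align_events(EventSeries(truth.breath_times, "breath"),
                                 onsets, pre=3.0, post_from_onset=4.0)
        psth = cr.build_psth(trials, stim_duration=1.0)
        assert psth.counts.sum() == sum(len(tr) for tr in trials)

    def test_edge_event_joins_later_bin(self):
        psth = cr.build_psth([np.array([0.1])], stim_duration=1.0)
        k = np.flatnonzero(psth.counts)[0]
        assert psth.edges[k] == pytest.approx(0.1)

    def test_bpm_unit_scales_by_60(self):
        tr = [np.arange(-3.0, 4.0, 0.1) + 0.05]
        hz = cr.build_psth(tr, 1.0, unit="Hz")
        bpm = cr.build_psth(tr, 1.0, unit="bpm")
        np.testing.assert_allclose(bpm.rate, 60.0 * hz.rate)


def regular_trials(rate_hz=10.0, pre=5.0, post=6.0, n_trials=1):
    iv = 1.0 / rate_hz
    rel = np.arange(-pre + iv / 2, post, iv)
    return [rel.copy() for _ in range(n_trials)]


class TestMaxChange:
    def test_unmodulated_regular_train_changes_zero_percent(self):
        mr = cr.mean_rate_series(regular_trials(), stim_duration=1.0)
        res = cr.max_rate_change(mr, stim_duration=1.0)
        assert res.change == pytest.approx(0.0, abs=1e-12)
        assert res.baseline_rate == pytest.approx(10.0)

    def test_full_apnea_drops_100_percent(self):
        rel = np.concatenate([np.arange(-4.95, 0.0, 0.1),
                              np.arange(2.05, 5.0, 0.1)])
        mr = cr.mean_rate_series([rel], stim_duration=1.0)
        res = cr.max_rate_change(mr, stim_duration=1.0)
        assert res.magnitude == pytest.approx(100.0, abs=1e-12)

    def test_partial_drop_arithmetic(self):
        # five trials at 10 Hz baseline; only two keep breathing through
        # the stimulus window -> mean rate 4 Hz during light: -60%
        outside = np.concatenate([np.arange(-4.95, 0.0, 0.1),
                                  np.arange(2.05, 5.0, 0.1)])
        inside = np.arange(0.05, 2.0, 0.1)
        trials = [np.sort(np.r_[outside, inside]) if k < 2 else outside
                  for k in range(5)]
        mr = cr.mean_rate_series(trials, stim_duration=1.0)
        res = cr.max_rate_change(mr, stim_duration=1.0, smooth_bins=1)
        assert res.change == pytest.approx(-60.0, abs=1e-9)

    def test_magnitude_bounded_for_drops(self, apnea_session):
        rec, truth = apnea_session
        from arrestlab import EventSeries
        onsets = np.array([w[0] for w in rec.stim_windows()])
        trials = cr.align_events(EventSeries(truth.breath_times, "breath"),
                                 onsets, pre=5.0, post_from_onset=6.0)
        res = cr.max_rate_change(cr.mean_rate_series(trials, 1.0), 1.0)
        assert 0.0 <= res.magnitude <= 100.0

    def test_zero_baseline_flagged(self):
        mr = cr.mean_rate_series([np.array([2.5])], stim_duration=1.0)
        with pytest.raises(ValueError):
            cr.max_rate_change(mr, stim_duration=1.0)


class TestZScoreAndEpochs:
    def test_constant_rate_zscore_zero(self):
        mr = cr.mean_rate_series(regular_trials(), stim_duration=1.0)
        z = cr.rate_zscore(mr)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_two_sd_excursion_scores_two(self):
        rng = np.random.default_rng(1)
        rate = np.r_[rng.choice([4.0, 6.0], 50), np.full(60, 5.0)]
        mu, sd = rate[:50].mean(), rate[:50].std()
        rate[70] = mu + 2 * sd
        mr = cr.RateSeries(edges=np.arange(-50, 61) * 0.1, rate=rate,
                           counts=rate * 0.1, n_trials=1, bin_width=0.1,
                           unit="Hz")
        z = cr.rate_zscore(mr, smooth_bins=1)
        assert z[70] == pytest.approx(2.0)

    def test_apnea_session_z_strongly_negative_then_recovers(self, apnea_session):
        rec, truth = apnea_session
        from arrestlab import EventSeries
        onsets = np.array([w[0] for w in rec.stim_windows()])
        trials = cr.align_events(EventSeries(truth.breath_times, "breath"),
                                 onsets, pre=5.0, post_from_onset=6.0)
        mr = cr.mean_rate_series(trials, 1.0)
        z = cr.rate_zscore(mr)
        stim = (mr.centers > 0.2) & (mr.centers < 0.8)
        late = mr.centers > 3.0
        assert z[stim].mean() < -1.0
        assert abs(z[late].mean()) < 1.5

    def test_epoch_averages(self):
        mr = cr.mean_rate_series(regular_trials(), stim_duration=1.0)
        out = cr.epoch_rate_averages(mr, stim_duration=1.0)
        for v in out.values():
            assert v == pytest.approx(10.0)

    def test_apnea_light_epoch_is_zero(self):
        rel = np.concatenate([np.arange(-4.95, 0.0, 0.1),
                              np.arange(1.05, 5.0, 0.1)])
        mr = cr.mean_rate_series([rel], stim_duration=1.0)
        out = cr.epoch_rate_averages(mr, stim_duration=1.0)
        assert out["light_on"] == 0.0
        assert out["before"] == pytest.approx(10.0)

    def test_incomplete_coverage_flagged(self):
        mr = cr.build_psth([np.array([0.5])], 1.0, pre=2.0, post=2.0)
        with pytest.raises(ValueError):
            cr.epoch_rate_averages(mr, stim_duration=1.0)
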