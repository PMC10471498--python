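"""Limb coordination: speeds, body-axis angle, phase estimation,
pause/play phase difference and step-cycle continuity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrestlab import gaitphase, synthio
from arrestlab.gaitphase import wrap_phase_deg

from conftest import make_trial, sinusoid_trial


def constant_trial(n=60, value=0.1):
    pos = {m: np.column_stack([np.full(n, value), np.zeros(n)])
           for m in ("LF", "RF", "LH", "RH", "B", "M")}
    return make_trial(pos, light_onset=0.1, light_offset=0.3)


class TestLimbSpeeds:
    def test_constant_positions_give_zero_speeds(self):
        speeds = gaitphase.estimate_limb_speeds(constant_trial())
        for m, s in speeds.s.items():
            assert np.all(s == 0.0), m
        assert np.all(speeds.s_mean == 0.0)

    def test_uniform_motion_speed_and_pair_means(self):
        n, sf = 120, 150.0
        x = np.arange(n) * 0.001  # 0.1 cm/frame -> 15 cm/s
        pos = {m: np.column_stack([x, np.zeros(n)])
               for m in ("LF", "RF", "LH", "RH", "B", "M")}
        speeds = gaitphase.estimate_limb_speeds(
            make_trial(pos, light_onset=0.1, light_offset=0.3))
        core = slice(20, -20)  # away from filter edge effects
        np.testing.assert_allclose(speeds.s["LF"][core], 15.0, rtol=1e-9)
        np.testing.assert_allclose(speeds.s_f[core], 15.0, rtol=1e-9)
        np.testing.assert_allclose(
            speeds.s_h, 0.5 * (speeds.s["LH"] + speeds.s["RH"]), rtol=1e-12)
        np.testing.assert_allclose(
            speeds.s_mean, np.mean([speeds.s[m] for m in speeds.s], axis=0),
            rtol=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            gaitphase.estimate_limb_speeds(constant_trial(n=20))


class TestBodyAxisAngle:
    def test_parallel_to_reference_is_zero(self):
        assert gaitphase.compute_body_axis_angle(
            (0.0, 0.0), (1.0, 0.0)) == 0.0

    def test_positive_slope_is_plus_45(self):
        assert gaitphase.compute_body_axis_angle(
            (0.0, 0.0), (1.0, 1.0)) == pytest.approx(45.0)

    def test_negative_slope_is_minus_45(self):
        assert gaitphase.compute_body_axis_angle(
            (0.0, 0.0), (1.0, -1.0)) == pytest.approx(-45.0)

    def test_zero_length_axis_rejected(self):
        with pytest.raises(ValueError):
            gaitphase.compute_body_axis_angle((0.5, 0.5), (0.5, 0.5))


class TestPhaseTrace:
    def test_synchronous_traces_give_zero_phase_flagged(self):
        trial = sinusoid_trial(offset_deg=0.0)
        phase = gaitphase.estimate_phase_trace(trial, "LFRF")
        assert phase.degenerate
        assert np.all(phase.phi == 0.0)

    def test_alternation_reaches_plus_180_at_max_displacement(self):
        trial = sinusoid_trial(offset_deg=180.0)
        phase = gaitphase.estimate_phase_trace(trial, "LFRF")
        d = trial.x("LF") - trial.x("RF")
        assert phase.phi[np.argmax(d)] == pytest.approx(180.0)
        assert phase.phi[np.argmin(d)] == pytest.approx(-180.0)
        assert np.all(np.abs(phase.phi) <= 180.0)

    def test_phase_flat_during_arrest(self, continue_trial):
        trial, truth = continue_trial
        phase = gaitphase.estimate_phase_trace(trial, "LFRF")
        hold = (phase.times >= truth.arrest_time) & \
               (phase.times < truth.resume_time)
        assert np.ptp(phase.phi[hold]) == 0.0

    @pytest.mark.parametrize("offset", [45.0, 90.0, 135.0, 180.0])
    def test_lag_mode_recovers_known_offset(self, offset):
        cfg = synthio.CorridorSimConfig(
            left_right_phase_offset=offset, light_onset=3.5,
            light_offset=3.8, arrest_latency=0.05, resume_latency=0.05,
            seed=0)
        trial, _ = synthio.gen_corridor_trial(cfg)
        phase = gaitphase.estimate_phase_trace(trial, "LFRF", mode="lag")
        pre = phase.times < 3.0  # undisturbed locomotion
        err = np.abs(wrap_phase_deg(phase.phi[pre] - offset))
        assert np.median(err) < 5.0

    def test_heading_rotation_with_correction_changes_phase_below_1deg(self):
        base = synthio.CorridorSimConfig(seed=21)
        rot = synthio.CorridorSimConfig(seed=21, heading_angle=8.0)
        t0, _ = synthio.gen_corridor_trial(base)
        t1, _ = synthio.gen_corridor_trial(rot)
        p0 = gaitphase.estimate_phase_trace(t0, "LFRF")
        p1 = gaitphase.estimate_phase_trace(t1, "LFRF")
        assert np.max(np.abs(p0.phi - p1.phi)) < 1.0


class TestPhaseDifference:
    def test_identical_phases_give_zero(self):
        trial = sinusoid_trial()
        phase = gaitphase.estimate_phase_trace(trial, "LFRF")
        assert gaitphase.pause_play_phase_difference(phase, 0.5, 0.5) == 0.0

    def test_wrapping_179_to_minus_179_is_plus_2(self):
        assert wrap_phase_deg(-179.0 - 179.0) == pytest.approx(2.0)
        assert wrap_phase_deg(180.0) == 180.0
        assert wrap_phase_deg(-180.0) == 180.0

    def test_times_outside_trace_rejected(self):
        phase = gaitphase.estimate_phase_trace(sinusoid_trial(), "LFRF")
        with pytest.raises(ValueError):
            gaitphase.pause_play_phase_difference(phase, -1.0, 0.5)


class TestContinuity:
    def _phase(self, phi, sf=150.0):
        return gaitphase.PhaseTrace(times=np.arange(len(phi)) / sf,
                                    phi=np.asarray(phi, dtype=float),
                                    pair="LFRF", mode="displacement")

    def test_matching_slope_signs_continuous(self):
        t = np.arange(600) / 150.0
        phase = self._phase(180 * np.sin(2 * np.pi * 1.0 * t))
        # pause on the rising flank, play on the next rising flank
        cont, m_pause, m_play = gaitphase.classify_continuity(
            phase, pause_time=1.1, play_time=2.1)
        assert (cont, np.sign(m_pause), np.sign(m_play)) == (1, 1.0, 1.0)

    def test_opposite_slope_signs_discontinuous(self):
        t = np.arange(600) / 150.0
        phase = self._phase(180 * np.sin(2 * np.pi * 1.0 * t))
        # pause rising, play falling
        cont, m_pause, m_play = gaitphase.classify_continuity(
            phase, pause_time=1.1, play_time=2.4)
        assert cont == 0
        assert np.sign(m_pause) != np.sign(m_play)

    def test_pause_at_peak_with_sign_switch_is_continuous(self):
        # an arrest that freezes the phase exactly at a cycle peak: zero
        # pre-pause slope, sign switch at play -> still continuous
        t = np.arange(600) / 150.0
        phi = 180 * np.sin(2 * np.pi * 1.0 * np.minimum(t, 0.25))
        hold_end = 0.8
        after = t >= hold_end
        phi[after] = 180 * np.sin(
            2 * np.pi * 1.0 * (t[after] - hold_end + 0.25))
        phase = self._phase(phi)
        cont, m_pause, m_play = gaitphase.classify_continuity(
            phase, pause_time=0.4, play_time=0.85)
        assert m_pause == 0.0
        assert np.sign(m_pause) != np.sign(m_play)
        assert cont == 1

    def test_missing_bracketing_extremum_unclassifiable(self):
        phase = self._phase(np.linspace(-170, 170, 300))
        cont, m_pause, m_play = gaitphase.classify_continuity(
            phase, pause_time=0.5, play_time=1.0)
        assert cont is None and m_pause is None and m_play is None


class TestPostureClassifiers:
    @pytest.mark.parametrize("area,expect", [
        (0.30, "mid-stance"),   # > 25% of max area
        (0.25, "swing"),        # exactly 25%: strict inequality
        (0.0, "swing"),
    ])
    def test_stance_rule(self, area, expect):
        assert gaitphase.classify_stance(area, 1.0) == expect

    def test_zero_max_area_rejected(self):
        with pytest.raises(ValueError):
            gaitphase.classify_stance(0.1, 0.0)

    @pytest.mark.parametrize("angle,expect", [
        (90.0, "aligned"), (104.0, "aligned"), (75.0, "aligned"),
        (110.0, "not aligned"), (60.0, "not aligned"),
    ])
    def test_alignment_band(self, angle, expect):
        assert gaitphase.classify_alignment(angle) == expect


class TestPausePlayPipeline:
    def test_continue_trial_scores_zero_delta_and_continuity(
            self, continue_trial):
        trial, _ = continue_trial
        for pair in ("LFRF", "LHRH"):
            res = gaitphase.score_pause_play(trial, pair=pair)
            assert not res.excluded
            assert res.delta_phi == 0.0
            assert res.continuity == 1

    def test_never_pausing_trial_is_excluded(self):
        cfg = synthio.CorridorSimConfig(
            light_onset=3.6, light_offset=3.7, arrest_latency=5.0,
            resume_latency=0.0, seed=0)
        # latency longer than the light window: clamped to light_offset,
        # leaving at most a 0.1-s hold; require a 0.3-s sustained pause
        trial, _ = synthio.gen_corridor_trial(cfg)
        speeds = gaitphase.estimate_limb_speeds(trial)
        res = gaitphase.detect_pause_play(speeds, 3.6, 3.7, "LFRF", n_s=45)
        assert res.excluded

    @settings(max_examples=20, deadline=None)
    @given(st.floats(-1000, 1000))
    def test_wrap_stays_in_half_open_interval(self, d):
        w = wrap_phase_deg(d)
        assert -180.0 < w <= 180.0
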