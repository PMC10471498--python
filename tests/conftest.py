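"""Shared fixtures: small synthetic sessions with known ground truth."""

import numpy as np
import pytest

from arrestlab import synthio
from arrestlab.datatypes import TrackedTrial


@pytest.fixture(scope="session")
def continue_trial():
    """A noiseless pause-and-play corridor trial with fixed latency."""
    cfg = synthio.CorridorSimConfig(seed=11)
    return synthio.gen_corridor_trial(cfg)


@pytest.fixture(scope="session")
def apnea_session():
    """A 40-s plethysmography session with two 1-s apnea-evoking stimuli."""
    cfg = synthio.PhysioSimConfig(
        session_duration=40.0, stim_onsets=(12.0, 28.0), seed=3)
    return synthio.gen_physio_session(cfg)


def make_trial(positions: dict, frame_rate=150.0, light_onset=2.0,
               light_offset=3.0) -> TrackedTrial:
    return TrackedTrial(positions=positions, frame_rate=frame_rate,
                        light_onset=light_onset, light_offset=light_offset)


def sinusoid_trial(
    n_frames=600,
    frame_rate=150.0,
    step_hz=4.0,
    amp=0.01,
    offset_deg=180.0,
    pairs=("LF", "RF", "LH", "RH"),
) -> TrackedTrial:
    """A stationary trial whose paws oscillate with a fixed left-right
    phase offset and whose body axis lies along the corridor."""
    t = np.arange(n_frames) / frame_rate
    th = 2 * np.pi * step_hz * t
    d = np.deg2rad(offset_deg)
    pos = {}
    for i, m in enumerate(pairs):
        phase = 0.0 if m.startswith("L") else -d
        y = 0.01 if m.startswith("L") else -0.01
        pos[m] = np.column_stack([amp * np.sin(th + phase), np.full(n_frames, y)])
    pos["B"] = np.column_stack([np.full(n_frames, -0.035), np.zeros(n_frames)])
    pos["M"] = np.column_stack([np.zeros(n_frames), np.zeros(n_frames)])
    return make_trial(pos, frame_rate=frame_rate)
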