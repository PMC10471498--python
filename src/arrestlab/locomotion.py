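"""Corridor-trial velocity computation and light-evoked arrest timing.

The chamber position (x coordinate of the perianal/tail-base marker) is
offset-corrected, downsampled to 150 frames/s, and differentiated to
velocity; tracking jitter is removed by zeroing velocities below
0.045 m/s. Arrest and resume times are then found with contiguity rules:
an arrest is the first zero-velocity frame after light onset that starts a
stable run of at least four zero frames (a run terminated inside the
light-on window by four or more contiguous non-zero frames is a transient
hesitation, not an arrest), and a resume is the first non-zero frame after
light offset that starts a run of at least four non-zero frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import TrackedTrial

__all__ = [
    "VelocityTrace",
    "ArrestTiming",
    "compute_velocity",
    "detect_arrest_timing",
    "smooth_for_plotting",
]

#: Jitter threshold (m/s): velocities strictly below this are set to 0.
JITTER_THRESHOLD = 0.045

#: Analysis frame rate after downsampling (frames/s).
ANALYSIS_FRAME_RATE = 150.0

#: Minimum run length (frames) for the arrest/resume contiguity rules.
MIN_RUN = 4


@dataclass
class VelocityTrace:
    """Per-frame velocity of the animal along the corridor.

    ``times`` are in seconds from trial start; velocity sample ``k`` is the
    finite difference between downsampled positions ``k`` and ``k+1``,
    timestamped at the earlier frame.
    """

    v: np.ndarray          # m/s, jitter-filtered (>= 0)
    times: np.ndarray      # s
    sf: float              # frames/s after downsampling
    light_onset: float
    light_offset: float


@dataclass
class ArrestTiming:
    """Arrest/resume times for one trial, light onset at ``light_onset``.

    ``latency_to_arrest`` is relative to light onset and
    ``latency_to_resume`` relative to light offset. ``excluded`` marks
    trials failing the 0.5-s pre/post trackability requirement (these carry
    no timing values).
    """

    arrest_time: float | None
    resume_time: float | None
    latency_to_arrest: float | None
    latency_to_resume: float | None
    time_immobile: float | None
    resumed: bool
    arrested: bool
    excluded: bool = False


def compute_velocity(
    track: TrackedTrial,
    marker: str = "B",
    jitter_threshold: float = JITTER_THRESHOLD,
    target_sf: float = ANALYSIS_FRAME_RATE,
) -> VelocityTrace:
    """Compute the jitter-filtered corridor velocity from one marker.

    Parameters
    ----------
    track
        Trial with marker positions in meters; the raw frame rate must be
        an integer multiple of ``target_sf``.
    marker
        Marker to use for chamber position (tail base by default, standing
        in for the perianal marker).
    """
    x = track.x(marker)
    if len(x) < 2:
        raise ValueError("track must contain at least 2 frames")
    factor = track.frame_rate / target_sf
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"frame rate {track.frame_rate} is not an integer multiple "
            f"of {target_sf}")
    factor = int(round(factor))

    x = x - x[0]                # offset correction
    x = x[::factor]             # downsample by decimation
    v = np.diff(x) * target_sf
    v = np.where(v < jitter_threshold, 0.0, v)
    times = np.arange(len(v)) / target_sf
    return VelocityTrace(
        v=v, times=times, sf=target_sf,
        light_onset=track.light_onset, light_offset=track.light_offset,
    )


def smooth_for_plotting(trace: VelocityTrace, window_s: float = 0.02) -> np.ndarray:
    """Centered rolling-average smoothing, for illustration only.

    Never applied before arrest/resume detection.
    """
    w = max(int(round(window_s * trace.sf)), 1)
    kernel = np.ones(w) / w
    return np.convolve(trace.v, kernel, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs in ``mask`` as (start, stop) index pairs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_arrest_timing(
    trace: VelocityTrace,
    min_run: int = MIN_RUN,
    min_margin_s: float = 0.5,
    observation_s: float = 1.5,
) -> ArrestTiming:
    """Detect arrest and resume times from a jitter-filtered velocity trace.

    Arrest: first frame after light onset with zero velocity that is inside
    a run of at least ``min_run`` contiguous zero frames, provided the run
    is not terminated within the light-on window by ``min_run`` or more
    contiguous non-zero frames. Resume: first frame after light offset with
    velocity > 0 inside a run of at least ``min_run`` contiguous non-zero
    frames, searched within ``observation_s`` after light offset.

    Trials without ``min_margin_s`` of coverage before and after the light
    window are flagged ``excluded`` rather than raising.
    """
    v, t = trace.v, trace.times
    onset, offset = trace.light_onset, trace.light_offset

    if t[0] > onset - min_margin_s + 1e-9 or t[-1] < offset + min_margin_s - 1e-9:
        return ArrestTiming(None, None, None, None, None,
                            resumed=False, arrested=False, excluded=True)

    on_idx = int(np.searchsorted(t, onset))
    off_idx = int(np.searchsorted(t, offset))

    # --- arrest ------------------------------------------------------------
    arrest_time: float | None = None
    zero = v == 0.0
    for start, stop in _runs(zero):
        first = max(start, on_idx)
        if first >= stop or stop - first < min_run:
            continue
        # reject a candidate terminated inside the light-on window by a
        # >= min_run contiguous non-zero run (a transient hesitation)
        if stop < off_idx:
            nz_stop = stop
            while nz_stop < len(v) and v[nz_stop] > 0:
                nz_stop += 1
            if nz_stop - stop >= min_run:
                continue
        arrest_time = float(t[first])
        break

    # --- resume ------------------------------------------------------------
    resume_time: float | None = None
    obs_end = offset + observation_s
    nonzero = v > 0.0
    for start, stop in _runs(nonzero):
        first = max(start, off_idx)
        if first >= stop or stop - first < min_run:
            continue
        if t[first] > obs_end + 1e-9:
            break
        resume_time = float(t[first])
        break

    arrested = arrest_time is not None
    resumed = resume_time is not None and arrested
    return ArrestTiming(
        arrest_time=arrest_time,
        resume_time=resume_time if resumed else None,
        latency_to_arrest=(arrest_time - onset) if arrested else None,
        latency_to_resume=(resume_time - offset) if resumed else None,
        time_immobile=(resume_time - arrest_time) if resumed else None,
        resumed=resumed,
        arrested=arrested,
    )
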