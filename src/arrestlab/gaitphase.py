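"""Limb-pair coordination: speeds, pause/play events, phase, continuity,
and arrest-posture classification.

The left-right coordination phase is measured two ways:

``displacement`` (default)
    The instantaneous phase is proportional to the left-right x-distance,
    ``phi(t) = 180 * d(t) / d_max``, where ``d(t)`` is the left-minus-right
    displacement after body-axis correction and ``d_max`` a per-trial
    robust maximum of ``|d|``. Maximum positive alternation maps to +180
    degrees, synchrony to 0, maximum negative alternation to -180. This
    definition gives a continuous trace that stays flat at its held value
    during an arrest.

``lag``
    The phase is measured from peak timing: ``phi = 360 * (t - t0) / T``,
    with ``t0`` the peak time of the first limb within a cycle, ``t`` the
    lag of the other limb's peak, and ``T`` the peak-to-peak cycle
    duration. This reproduces the textbook lag formula but is only defined
    cycle-by-cycle.

Both are kept because a continuous trace is required for pause/play phase
differences and step-cycle continuity, while the lag form is the natural
check that a known left-right phase offset is recovered.

Speed samples are forward differences stamped at the interval-start frame:
sample ``k`` describes movement over ``[k, k+1)``. With this convention the
pause event (first sustained below-threshold sample after light onset) and
the play event (first sustained above-threshold sample after light offset)
both index frames whose *positions* are still at the held posture, so the
pause-play phase difference of an uninterrupted pause-and-play trial is
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .datatypes import TrackedTrial

__all__ = [
    "LimbSpeeds",
    "PhaseTrace",
    "PausePlayResult",
    "estimate_limb_speeds",
    "detect_pause_play",
    "compute_body_axis_angle",
    "estimate_phase_trace",
    "pause_play_phase_difference",
    "classify_continuity",
    "classify_stance",
    "classify_alignment",
    "wrap_phase_deg",
]

PAIRS = {"LFRF": ("LF", "RF"), "LHRH": ("LH", "RH")}

#: Position moving-average window (frames) applied before speed estimation.
SPEED_FILTER_FRAMES = 30

#: Default pause-speed threshold (cm/s) and sustained-run length (frames).
PAUSE_SPEED_THRESHOLD = 0.5
PAUSE_MIN_RUN = 4

#: Prominence floor (degrees) for peak/trough detection on phase traces.
PHASE_PEAK_PROMINENCE = 20.0


def wrap_phase_deg(d: np.ndarray | float) -> np.ndarray | float:
    """Wrap a phase difference in degrees to (-180, 180]."""
    w = (np.asarray(d, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(d) else w


@dataclass
class LimbSpeeds:
    """Per-marker instantaneous speeds (cm/s) and their pair averages.

    ``s[m][k]`` is the signed x-speed of marker ``m`` over frame interval
    ``[k, k+1)``; ``s_mean`` averages the six markers, ``s_f``/``s_h`` the
    fore/hind pairs.
    """

    s: dict[str, np.ndarray]
    s_mean: np.ndarray
    s_f: np.ndarray
    s_h: np.ndarray
    times: np.ndarray
    frame_rate: float

    def pair_speed(self, pair: str) -> np.ndarray:
        if pair == "LFRF":
            return self.s_f
        if pair == "LHRH":
            return self.s_h
        raise KeyError(f"unknown limb pair {pair!r}")


@dataclass
class PhaseTrace:
    """Continuous coordination phase for one limb pair, degrees in
    [-180, 180]."""

    times: np.ndarray
    phi: np.ndarray
    pair: str
    mode: str
    degenerate: bool = False  # no left-right displacement anywhere

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.phi))


@dataclass
class PausePlayResult:
    """Pause/play timing and phase bookkeeping for one limb pair."""

    pair: str
    pause_time: float | None
    play_time: float | None
    phi_pause: float | None = None
    phi_play: float | None = None
    delta_phi: float | None = None
    m_pause: float | None = None
    m_play: float | None = None
    continuity: int | None = None
    excluded: bool = False


def estimate_limb_speeds(
    track: TrackedTrial,
    filter_frames: int = SPEED_FILTER_FRAMES,
) -> LimbSpeeds:
    """Instantaneous marker speeds after a moving-window position filter.

    Positions are smoothed with a centered moving average of
    ``filter_frames`` frames to suppress frame-to-frame tracking noise,
    then differentiated. Speeds are in cm/s, signed along x.
    """
    if track.n_frames < filter_frames:
        raise ValueError(
            f"trial has {track.n_frames} frames; need >= {filter_frames}")
    sf = track.frame_rate
    s: dict[str, np.ndarray] = {}
    for m in ("LF", "RF", "LH", "RH", "B", "M"):
        x = uniform_filter1d(track.x(m), size=filter_frames, mode="nearest")
        s[m] = np.diff(x) * sf * 100.0  # m -> cm
    s_mean = np.mean([s[m] for m in s], axis=0)
    s_f = 0.5 * (s["LF"] + s["RF"])
    s_h = 0.5 * (s["LH"] + s["RH"])
    times = np.arange(len(s_f)) / sf
    return LimbSpeeds(s=s, s_mean=s_mean, s_f=s_f, s_h=s_h,
                      times=times, frame_rate=sf)


def _first_sustained(mask: np.ndarray, start: int, min_run: int) -> int | None:
    """Index of the first True at/after ``start`` inside a run of at least
    ``min_run`` contiguous True samples."""
    k = start
    n = len(mask)
    while k < n:
        if mask[k]:
            stop = k
            while stop < n and mask[stop]:
                stop += 1
            if stop - k >= min_run:
                return k
            k = stop
        else:
            k += 1
    return None


def detect_pause_play(
    speeds: LimbSpeeds,
    light_onset: float,
    light_offset: float,
    pair: str = "LFRF",
    eps_s: float = PAUSE_SPEED_THRESHOLD,
    n_s: int = PAUSE_MIN_RUN,
) -> PausePlayResult:
    """Detect pause and play events from a limb-pair speed trace.

    Pause: first sample at/after light onset with ``|speed| < eps_s``
    sustained for at least ``n_s`` samples. Play: first sample at/after
    light offset with ``|speed| >= eps_s`` sustained for at least ``n_s``
    samples. Trials with no qualifying pause (or play) are flagged
    ``excluded`` rather than raising.
    """
    sp = np.abs(speeds.pair_speed(pair))
    t = speeds.times
    on_idx = int(np.searchsorted(t, light_onset))
    off_idx = int(np.searchsorted(t, light_offset))

    below = sp < eps_s if eps_s > 0 else sp == 0.0
    pause_idx = _first_sustained(below, on_idx, n_s)
    play_idx = _first_sustained(~below, off_idx, n_s)
    if pause_idx is None or play_idx is None:
        return PausePlayResult(pair=pair, pause_time=None, play_time=None,
                               excluded=True)
    return PausePlayResult(pair=pair,
                           pause_time=float(t[pause_idx]),
                           play_time=float(t[play_idx]))


def compute_body_axis_angle(
    p_b: np.ndarray,
    p_m: np.ndarray,
    r: np.ndarray = (1.0, 0.0),
) -> np.ndarray | float:
    """Signed angle (degrees) between the body axis and the corridor axis.

    The body axis is ``b = p_m - p_b`` (tail base to trunk midpoint). The
    unsigned angle comes from ``arccos(b.r / (|b| |r|))`` and the sign from
    the slope of ``b`` relative to ``r``: positive slope gives a positive
    angle, negative slope a negative one. Accepts single vectors or
    ``(n, 2)`` arrays.
    """
    b = np.atleast_2d(np.asarray(p_m, dtype=float) - np.asarray(p_b, dtype=float))
    r = np.asarray(r, dtype=float)
    nb = np.hypot(b[:, 0], b[:, 1])
    nr = np.hypot(r[0], r[1])
    if np.any(nb == 0) or nr == 0:
        raise ValueError("zero-length body axis or reference vector")
    cosang = np.clip((b @ r) / (nb * nr), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    # slope sign of b relative to r = sign of the z-component of r x b
    cross = r[0] * b[:, 1] - r[1] * b[:, 0]
    signed = np.where(cross >= 0, ang, -ang)
    return float(signed[0]) if signed.size == 1 else signed


def _refined_peak_times(
    y: np.ndarray, times: np.ndarray, **peak_kw
) -> np.ndarray:
    """Peak times with sub-frame quadratic refinement."""
    idx, _ = find_peaks(y, **peak_kw)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    out = []
    for i in idx:
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            shift = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            out.append(times[i] + np.clip(shift, -0.5, 0.5) * dt)
        else:
            out.append(times[i])
    return np.asarray(out)


def estimate_phase_trace(
    track: TrackedTrial,
    pair: str = "LFRF",
    mode: str = "displacement",
    body_axis: str | None = "projection",
    robust_q: float = 0.995,
) -> PhaseTrace:
    """Estimate the left-right coordination phase for a limb pair.

    Parameters
    ----------
    mode
        ``"displacement"`` (default) or ``"lag"`` (see module docstring).
    body_axis
        How to correct for the body axis deviating from the corridor axis:
        ``"projection"`` projects the left-right separation onto the
        instantaneous body axis (geometrically exact, invariant to whole-
        trial rotation); ``"additive"`` adds the signed body-axis angle to
        the phase at each time step, reproducing the additive correction
        convention; ``None`` disables the correction.
    robust_q
        Quantile of ``|d|`` used as the per-trial maximum displacement.
    """
    if pair not in PAIRS:
        raise KeyError(f"unknown limb pair {pair!r}")
    left, right = PAIRS[pair]
    t = track.times
    p_l = track.positions[left]
    p_r = track.positions[right]

    if mode == "displacement":
        if body_axis == "projection":
            b = track.positions["M"] - track.positions["B"]
            nb = np.hypot(b[:, 0], b[:, 1])
            if np.any(nb == 0):
                raise ValueError("zero-length body axis")
            bhat = b / nb[:, None]
            sep = p_l - p_r
            d = sep[:, 0] * bhat[:, 0] + sep[:, 1] * bhat[:, 1]
        else:
            d = p_l[:, 0] - p_r[:, 0]
        d_max = float(np.quantile(np.abs(d), robust_q))
        if d_max == 0.0:
            # no left-right displacement anywhere: synchronous by
            # convention, flagged degenerate
            return PhaseTrace(times=t, phi=np.zeros_like(d), pair=pair,
                              mode=mode, degenerate=True)
        phi = np.clip(180.0 * d / d_max, -180.0, 180.0)
        if body_axis == "additive":
            phi_body = compute_body_axis_angle(
                track.positions["B"], track.positions["M"])
            phi = wrap_phase_deg(phi + np.atleast_1d(phi_body))
        return PhaseTrace(times=t, phi=phi, pair=pair, mode=mode)

    if mode == "lag":
        # oscillatory displacement relative to the trunk, per limb
        xm = track.x("M")
        y_l = p_l[:, 0] - xm
        y_r = p_r[:, 0] - xm
        amp = 0.25 * (np.ptp(y_l) + np.ptp(y_r))
        peaks_l = _refined_peak_times(y_l, t, prominence=0.5 * amp)
        peaks_r = _refined_peak_times(y_r, t, prominence=0.5 * amp)
        if len(peaks_l) < 2 or len(peaks_r) < 1:
            return PhaseTrace(times=t, phi=np.zeros_like(t), pair=pair,
                              mode=mode, degenerate=True)
        phases = []
        cyc_t = []
        for t0, t1 in zip(peaks_l[:-1], peaks_l[1:]):
            period = t1 - t0
            inside = peaks_r[(peaks_r >= t0) & (peaks_r < t1)]
            if len(inside) == 0 or period <= 0:
                continue
            lag = inside[0] - t0
            phases.append(wrap_phase_deg(360.0 * lag / period))
            cyc_t.append(0.5 * (t0 + t1))
        if not phases:
            return PhaseTrace(times=t, phi=np.zeros_like(t), pair=pair,
                              mode=mode, degenerate=True)
        # interpolate circularly: unwrap so values near +/-180 do not sweep
        # through 0 between cycles
        unwrapped = np.degrees(np.unwrap(np.radians(np.asarray(phases))))
        phi = wrap_phase_deg(np.interp(t, np.asarray(cyc_t), unwrapped))
        if body_axis == "additive":
            phi_body = compute_body_axis_angle(
                track.positions["B"], track.positions["M"])
            phi = wrap_phase_deg(phi + np.atleast_1d(phi_body))
        return PhaseTrace(times=t, phi=phi, pair=pair, mode=mode)

    raise ValueError(f"unknown mode {mode!r}")


def pause_play_phase_difference(
    phase: PhaseTrace, pause_time: float, play_time: float
) -> float:
    """Phase at play minus phase at pause, wrapped to (-180, 180]."""
    t0, t1 = phase.times[0], phase.times[-1]
    if not (t0 <= pause_time <= t1 and t0 <= play_time <= t1):
        raise ValueError("pause/play times fall outside the phase trace")
    return wrap_phase_deg(phase.at(play_time) - phase.at(pause_time))


def _extrema_times(phase: PhaseTrace,
                   prominence: float = PHASE_PEAK_PROMINENCE) -> np.ndarray:
    """Times of phase peaks and troughs above the prominence floor.

    A peak/trough held flat through an arrest is timed at its left edge,
    so an arrest landing on an extremum sees that extremum as the
    immediately preceding one (giving a near-zero pre-pause slope).
    """
    idx = []
    for sign in (1.0, -1.0):
        _, props = find_peaks(sign * phase.phi, prominence=prominence,
                              plateau_size=(1, None))
        idx.extend(props["left_edges"].tolist())
    return np.sort(phase.times[np.asarray(idx, dtype=int)])


def classify_continuity(
    phase: PhaseTrace,
    pause_time: float,
    play_time: float,
    eps_slope: float = 0.1,
    prominence: float = PHASE_PEAK_PROMINENCE,
) -> tuple[int | None, float | None, float | None]:
    """Binary step-cycle continuity from phase slopes around the hold.

    ``m_pause`` is the mean slope between the previous phase peak/trough
    and the pause event; ``m_play`` between the play event and the next
    peak/trough. Continuity is 1 when the slope signs agree (the cycle
    resumed its course), 1 when the pause landed on a peak/trough
    (``|m_pause|`` below ``eps_slope`` times the trial's maximum
    inter-extremum slope) so a sign switch is the natural continuation, and
    0 otherwise. Returns ``(continuity, m_pause, m_play)``;
    ``(None, None, None)`` when no bracketing extremum exists.
    """
    ext = _extrema_times(phase, prominence)
    prev = ext[ext < pause_time]
    nxt = ext[ext > play_time]
    if len(prev) == 0 or len(nxt) == 0:
        return None, None, None
    t_prev, t_next = prev[-1], nxt[0]
    m_pause = (phase.at(pause_time) - phase.at(t_prev)) / (pause_time - t_prev)
    m_play = (phase.at(t_next) - phase.at(play_time)) / (t_next - play_time)

    # reference scale: steepest mean slope between consecutive extrema
    ref = 0.0
    if len(ext) >= 2:
        vals = np.array([phase.at(tt) for tt in ext])
        ref = float(np.max(np.abs(np.diff(vals) / np.diff(ext))))
    if ref == 0.0:
        ref = max(abs(m_pause), abs(m_play), 1e-12)

    if np.sign(m_pause) == np.sign(m_play):
        cont = 1
    elif abs(m_pause) < eps_slope * ref:
        cont = 1  # arrest at a peak/trough: sign switch is the natural course
    else:
        cont = 0
    return cont, float(m_pause), float(m_play)


def classify_stance(paw_area: float, max_paw_area: float) -> str:
    """Mid-stance vs swing from paw-floor contact area.

    Mid-stance requires the contact area to exceed 25% of the reference
    full-contact paw area (strict inequality).
    """
    if max_paw_area <= 0:
        raise ValueError("max_paw_area must be positive")
    if paw_area < 0:
        raise ValueError("areas must be >= 0")
    return "mid-stance" if paw_area > 0.25 * max_paw_area else "swing"


def classify_alignment(angle_deg: float) -> str:
    """Aligned iff the body-axis-to-hind-paws angle is within 90 +/- 15
    degrees."""
    return "aligned" if 75.0 <= angle_deg <= 105.0 else "not aligned"


def score_pause_play(
    track: TrackedTrial,
    pair: str = "LFRF",
    eps_s: float = PAUSE_SPEED_THRESHOLD,
    n_s: int = PAUSE_MIN_RUN,
    eps_slope: float = 0.1,
) -> PausePlayResult:
    """Full per-trial pause-and-play scoring for one limb pair.

    Runs speed estimation, pause/play detection, displacement-mode phase
    estimation, phase difference, and continuity classification.
    """
    speeds = estimate_limb_speeds(track)
    res = detect_pause_play(speeds, track.light_onset, track.light_offset,
                            pair=pair, eps_s=eps_s, n_s=n_s)
    if res.excluded:
        return res
    phase = estimate_phase_trace(track, pair=pair, mode="displacement")
    res.phi_pause = phase.at(res.pause_time)
    res.phi_play = phase.at(res.play_time)
    res.delta_phi = pause_play_phase_difference(
        phase, res.pause_time, res.play_time)
    cont, m_pause, m_play = classify_continuity(
        phase, res.pause_time, res.play_time, eps_slope=eps_slope)
    res.continuity, res.m_pause, res.m_play = cont, m_pause, m_play
    return res
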