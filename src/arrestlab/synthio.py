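"""Synthetic session generators with known ground truth.

The study's animal recordings are not publicly deposited, so every analysis
in this package is exercised against synthetic sessions that emulate the
statistical structure the analyses assume: alternating sinusoidal left-right
paw displacement with forward translation and a light-triggered hold,
breathing as an event train (~4.8 Hz) with stimulus-locked apnea and a
post-stimulus rebound, a cardiac event train (~646 bpm) with late
bradycardia, activity traces crossing an inactivity threshold, stimulation
trains with uniform 45-90 s intervals gated on instantaneous activity, and
anatomical spot fields with a known colocalized fraction.

None of the distributional choices here is a generative model of the real
data; they are documented stand-ins that make parameter-recovery tests
possible (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import EventSeries, GroundTruth, PhysioRecording, TrackedTrial

__all__ = [
    "CorridorSimConfig",
    "PhysioSimConfig",
    "CylinderSimConfig",
    "AnesthetizedSimConfig",
    "CylinderSession",
    "gen_corridor_trial",
    "gen_physio_session",
    "gen_cylinder_session",
    "gen_anesthetized_recording",
    "gen_spot_field",
]


# ---------------------------------------------------------------------------
# Corridor trials
# ---------------------------------------------------------------------------

@dataclass
class CorridorSimConfig:
    """Configuration for a synthetic linear-corridor trial.

    The trial is a mouse translating at ``forward_speed`` with paw
    x-displacements oscillating sinusoidally at ``step_frequency``; a light
    window triggers a full-body hold after ``arrest_latency`` and movement
    resumes ``resume_latency`` after light offset. In ``continue`` mode
    (pause-and-play) the oscillation resumes at the frozen phase; in
    ``reset`` mode it restarts at a uniformly random phase.
    """

    frame_rate: float = 150.0
    trial_duration: float = 4.0
    forward_speed: float = 0.3            # m/s
    step_frequency: float = 4.0           # Hz
    left_right_phase_offset: float = 180.0  # degrees
    light_onset: float = 2.0              # s
    light_offset: float = 3.0             # s
    arrest_latency_mean: float = 0.11083  # s, in-vivo default
    arrest_latency_sd: float = 0.04401    # s, in-vivo default
    arrest_latency: float | None = None   # fixed value overrides the draw
    resume_latency: float = 0.14833       # s
    resume_mode: str = "continue"         # "continue" | "reset"
    postural_drift_amp: float = 0.0       # m, displacement during the hold
    tracking_noise_sd: float = 0.0        # m
    heading_angle: float = 0.0            # degrees, body axis vs corridor
    step_amplitude: float = 0.01          # m, paw oscillation amplitude
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0 <= self.light_onset < self.light_offset <= self.trial_duration):
            raise ValueError("light window must lie inside the trial")
        if self.tracking_noise_sd < 0:
            raise ValueError("tracking_noise_sd must be >= 0")
        if self.resume_latency < 0:
            raise ValueError("resume_latency must be >= 0")
        if self.arrest_latency is not None and self.arrest_latency < 0:
            raise ValueError("arrest_latency must be >= 0")
        if self.resume_mode not in ("continue", "reset"):
            raise ValueError(f"unknown resume_mode {self.resume_mode!r}")


# Marker geometry in the body frame (meters): lateral y-offsets of the paws
# and longitudinal placement of tail base (B) and trunk midpoint (M).
_PAW_Y = {"LF": 0.012, "RF": -0.012, "LH": 0.010, "RH": -0.010}
_PAW_X0 = {"LF": 0.030, "RF": 0.030, "LH": -0.020, "RH": -0.020}
_BODY_X0 = {"B": -0.035, "M": 0.0}


def _draw_arrest_latency(cfg: CorridorSimConfig, rng: np.random.Generator) -> float:
    if cfg.arrest_latency is not None:
        return float(cfg.arrest_latency)
    if cfg.arrest_latency_sd == 0:
        return float(max(cfg.arrest_latency_mean, 0.0))
    # truncated normal at 0 by redraw
    for _ in range(1000):
        lat = rng.normal(cfg.arrest_latency_mean, cfg.arrest_latency_sd)
        if lat >= 0:
            return float(lat)
    return 0.0


def gen_corridor_trial(cfg: CorridorSimConfig) -> tuple[TrackedTrial, GroundTruth]:
    """Generate one corridor trial with six marker tracks and ground truth.

    Returns a :class:`TrackedTrial` with markers LF, RF, LH, RH, B, M and a
    :class:`GroundTruth` carrying the true arrest/resume times, the
    left-right phase offset and the phase state at the hold.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    latency = _draw_arrest_latency(cfg, rng)
    t_arrest = cfg.light_onset + latency
    t_resume = cfg.light_offset + cfg.resume_latency
    if t_arrest > cfg.light_offset:
        t_arrest = cfg.light_offset  # latency cannot outlast the stimulus
    if t_resume >= cfg.trial_duration:
        raise ValueError("resume time falls outside the trial")

    n = int(round(cfg.trial_duration * cfg.frame_rate))
    t = np.arange(n) / cfg.frame_rate

    # Effective time tau: frozen during the hold, then continued with the
    # hold duration cut out, so both translation and oscillation resume from
    # the frozen state.
    hold = (t >= t_arrest) & (t < t_resume)
    after = t >= t_resume
    tau = t.copy()
    tau[hold] = t_arrest
    tau[after] = t[after] - (t_resume - t_arrest)

    # Oscillation phase. In reset mode the paws reposition smoothly during
    # the hold to a posture at a uniformly random new phase (small postural
    # readjustment under the light), and the cycle resumes from that new
    # phase; the tail-base/trunk markers and the forward position stay
    # frozen throughout the hold.
    theta = 2 * np.pi * cfg.step_frequency * tau
    reset_shift = 0.0
    if cfg.resume_mode == "reset":
        reset_shift = rng.uniform(0, 2 * np.pi)
        span = cfg.light_offset - t_arrest
        rep0 = t_arrest + 0.30 * span
        rep1 = t_arrest + 0.55 * span
        ramp = np.clip((t - rep0) / (rep1 - rep0), 0.0, 1.0)
        ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)  # smooth 0 -> 1
        ramp[~hold & ~after] = 0.0
        ramp[after] = 1.0
        theta = theta + reset_shift * ramp

    delta = np.deg2rad(cfg.left_right_phase_offset)
    pair_phase = {"LF": 0.0, "RF": -delta, "LH": np.pi / 2, "RH": np.pi / 2 - delta}

    x0 = cfg.forward_speed * tau

    positions: dict[str, np.ndarray] = {}
    for m in ("LF", "RF", "LH", "RH"):
        x = x0 + _PAW_X0[m] + cfg.step_amplitude * np.sin(theta + pair_phase[m])
        y = np.full(n, _PAW_Y[m])
        positions[m] = np.column_stack([x, y])
    for m in ("B", "M"):
        positions[m] = np.column_stack([x0 + _BODY_X0[m], np.zeros(n)])

    # Postural drift: small displacement during the hold with a half-sine
    # envelope so the trace stays continuous at the hold edges.
    if cfg.postural_drift_amp > 0 and hold.any():
        env = np.zeros(n)
        env[hold] = np.sin(np.pi * (t[hold] - t_arrest) / (t_resume - t_arrest))
        for m in positions:
            direction = rng.uniform(0, 2 * np.pi)
            drift = cfg.postural_drift_amp * env
            positions[m] = positions[m] + np.column_stack(
                [drift * np.cos(direction), drift * np.sin(direction)]
            )

    # Heading: rotate the whole trial so the body axis makes heading_angle
    # with the corridor axis (exercises the body-axis correction path).
    if cfg.heading_angle != 0.0:
        a = np.deg2rad(cfg.heading_angle)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        for m in positions:
            positions[m] = positions[m] @ rot.T

    if cfg.tracking_noise_sd > 0:
        for m in positions:
            positions[m] = positions[m] + rng.normal(
                0, cfg.tracking_noise_sd, positions[m].shape
            )

    trial = TrackedTrial(
        positions=positions,
        frame_rate=cfg.frame_rate,
        light_onset=cfg.light_onset,
        light_offset=cfg.light_offset,
    )
    truth = GroundTruth(
        arrest_time=t_arrest,
        resume_time=t_resume,
        phase_offset_deg=cfg.left_right_phase_offset,
        extra={
            "arrest_latency": latency,
            "resume_latency": cfg.resume_latency,
            "resume_mode": cfg.resume_mode,
            "reset_shift_rad": reset_shift,
            "step_frequency": cfg.step_frequency,
        },
    )
    return trial, truth


# ---------------------------------------------------------------------------
# Plethysmography / ECG / activity sessions
# ---------------------------------------------------------------------------

@dataclass
class PhysioSimConfig:
    """Configuration for a synthetic plethysmography + ECG + activity session.

    Breathing is an event train at ``baseline_resp_rate`` with a
    stimulus-locked effect (apnea by default) and a post-stimulus rebound;
    the heart is an independent event train at ``baseline_heart_rate`` with
    a late rate drop of ``heart_drop_fraction``. Stimulation is either given
    explicitly (``stim_onsets``) or generated with a uniform inter-stimulus
    interval drawn from ``iti_range``, gated on instantaneous activity
    exceeding ``activity_gate``.
    """

    sample_rate: float = 1000.0
    session_duration: float = 60.0
    baseline_resp_rate: float = 4.79      # Hz
    baseline_heart_rate: float = 646.0    # bpm
    stim_onsets: tuple[float, ...] | None = None
    stim_duration: float = 1.0            # s
    n_stims: int = 0                      # used when stim_onsets is None
    resp_effect: str = "apnea"            # apnea|slowing|tachypnea_then_slowing|none
    slowing_factor: float = 0.25          # rate multiplier for "slowing"
    rebound_rate: float = 6.16            # Hz, post-stimulus rebound
    rebound_duration: float = 1.0         # s
    heart_drop_fraction: float = 0.11     # fractional late-stimulus HR drop
    activity_threshold: float = 0.5       # ground-truth inactivity threshold, %
    active_level: float = 2.0             # baseline activity, %
    inactive_level: float = 0.05          # activity during arrest, %
    iti_range: tuple[float, float] = (45.0, 90.0)
    activity_gate: float = 0.1            # %, stimulation gate
    resp_jitter: float = 0.0              # fractional sd of breath intervals
    heart_jitter: float = 0.0
    noise_sd: float = 0.0                 # additive noise on flow and ecg
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_resp_rate <= 0 or self.baseline_heart_rate <= 0:
            raise ValueError("rates must be positive")
        if not (0.0 <= self.heart_drop_fraction <= 1.0):
            raise ValueError("heart_drop_fraction must lie in [0, 1]")
        if self.iti_range[0] >= self.iti_range[1]:
            raise ValueError("iti_range min must be < max")
        if self.resp_effect not in (
            "apnea", "slowing", "tachypnea_then_slowing", "none"
        ):
            raise ValueError(f"unknown resp_effect {self.resp_effect!r}")


def _event_train(
    rate_hz: float,
    t_start: float,
    t_stop: float,
    jitter: float,
    rng: np.random.Generator,
) -> list[float]:
    """Renewal event train with fractional interval jitter."""
    times: list[float] = []
    base = 1.0 / rate_hz
    t = t_start
    while t < t_stop:
        times.append(t)
        iv = base * (1.0 + jitter * rng.standard_normal()) if jitter > 0 else base
        t += max(iv, 0.2 * base)
    return times


def _resp_event_times(
    cfg: PhysioSimConfig,
    windows: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    breaths = _event_train(
        cfg.baseline_resp_rate, 0.25, cfg.session_duration - 0.1,
        cfg.resp_jitter, rng,
    )
    if cfg.resp_effect == "none" or not windows:
        return np.asarray(breaths)

    times = np.asarray(breaths)
    for on, off in windows:
        if cfg.resp_effect == "apnea":
            keep = (times < on) | (times >= off)
            times = times[keep]
            inserted: list[float] = []
        elif cfg.resp_effect == "slowing":
            keep = (times < on) | (times >= off)
            times = times[keep]
            inserted = _event_train(
                cfg.baseline_resp_rate * cfg.slowing_factor,
                on + 0.5 / (cfg.baseline_resp_rate * cfg.slowing_factor),
                off, cfg.resp_jitter, rng,
            )
        else:  # tachypnea_then_slowing
            keep = (times < on) | (times >= off)
            times = times[keep]
            split = on + 0.4 * (off - on)
            fast = _event_train(
                cfg.baseline_resp_rate * 1.5, on + 0.05, split,
                cfg.resp_jitter, rng,
            )
            slow = _event_train(
                cfg.baseline_resp_rate * cfg.slowing_factor, split, off,
                cfg.resp_jitter, rng,
            )
            inserted = fast + slow
        # rebound after light off, then baseline resumes
        reb_end = off + cfg.rebound_duration
        keep = (times < off) | (times >= reb_end)
        times = times[keep]
        rebound = [
            off + (k + 1) / cfg.rebound_rate
            for k in range(int(np.floor(cfg.rebound_duration * cfg.rebound_rate)))
        ]
        times = np.sort(np.concatenate([times, inserted, rebound]))
    # enforce a physiological refractory floor (breathing tops out near
    # 9 Hz), which also resolves collisions at rebound/baseline junctions
    out = [times[0]] if len(times) else []
    for tt in times[1:]:
        if tt - out[-1] >= 0.11:
            out.append(tt)
    return np.asarray(out)


def _beat_event_times(
    cfg: PhysioSimConfig,
    windows: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Cardiac train; the rate drop develops late in the stimulus and
    extends slightly past light off (slow cardiac dynamics)."""
    base_iv = 60.0 / cfg.baseline_heart_rate
    slow_iv = base_iv / max(1.0 - cfg.heart_drop_fraction, 1e-6)
    times: list[float] = []
    t = 0.05
    while t < cfg.session_duration - 0.05:
        times.append(t)
        iv = base_iv
        for on, off in windows:
            if on + 0.5 * (off - on) <= t < off + 0.5:
                iv = slow_iv
                break
        if cfg.heart_jitter > 0:
            iv *= 1.0 + cfg.heart_jitter * rng.standard_normal()
        t += max(iv, 0.3 * base_iv)
    return np.asarray(times)


def _add_pulses(
    trace: np.ndarray,
    event_times: np.ndarray,
    sample_rate: float,
    amp: float,
    sd_s: float,
    center_shift_s: float = 0.0,
) -> None:
    """Add Gaussian pulses in place, windowed to +/-4 sd around each event."""
    n = len(trace)
    half = int(np.ceil(4 * sd_s * sample_rate))
    grid = np.arange(-half, half + 1) / sample_rate
    pulse = amp * np.exp(-0.5 * (grid / sd_s) ** 2)
    for t_ev in event_times:
        c = int(round((t_ev + center_shift_s) * sample_rate))
        lo, hi = c - half, c + half + 1
        plo = max(0, -lo)
        phi = len(pulse) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            trace[lo:hi] += pulse[plo:phi]


def gen_physio_session(cfg: PhysioSimConfig) -> tuple[PhysioRecording, GroundTruth]:
    """Generate a synchronized flow/ECG/activity/stim session.

    The flow trace is synthesized from the breath event train as a
    stereotyped biphasic pulse per breath with the inspiratory (negative)
    extremum exactly at the event time; absolute flow units are arbitrary.
    The ECG is a sharp positive deflection at each beat time.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.session_duration * cfg.sample_rate))

    # --- stimulation windows ---------------------------------------------
    if cfg.stim_onsets is not None:
        windows = [(float(on), float(on) + cfg.stim_duration)
                   for on in cfg.stim_onsets]
    else:
        windows = []
        t = 5.0 + rng.uniform(*cfg.iti_range) - cfg.iti_range[0]
        while len(windows) < cfg.n_stims:
            t += rng.uniform(*cfg.iti_range)
            if t + cfg.stim_duration + cfg.rebound_duration + 5.0 > cfg.session_duration:
                break
            # gate: only stimulate if the instantaneous activity (active
            # baseline unless a previous stimulus is still suppressing it)
            # exceeds the gate
            suppressed = any(
                on <= t < off + 0.3 for on, off in windows
            )
            level = cfg.inactive_level if suppressed else cfg.active_level
            if level > cfg.activity_gate:
                windows.append((t, t + cfg.stim_duration))
    for on, off in windows:
        if on < 0 or off > cfg.session_duration:
            raise ValueError("stimulation window outside the session")

    # --- event trains ------------------------------------------------------
    breath_times = _resp_event_times(cfg, windows, rng)
    beat_times = _beat_event_times(cfg, windows, rng)

    # --- traces ------------------------------------------------------------
    flow = np.zeros(n)
    _add_pulses(flow, breath_times, cfg.sample_rate, amp=-1.0, sd_s=0.015)
    _add_pulses(flow, breath_times, cfg.sample_rate, amp=0.45, sd_s=0.020,
                center_shift_s=0.055)
    ecg = np.zeros(n)
    _add_pulses(ecg, beat_times, cfg.sample_rate, amp=1.0, sd_s=0.0015)
    if cfg.noise_sd > 0:
        flow += rng.normal(0, cfg.noise_sd, n)
        ecg += rng.normal(0, cfg.noise_sd, n)

    times = np.arange(n) / cfg.sample_rate
    activity = np.full(n, cfg.active_level)
    stim = np.zeros(n)
    for on, off in windows:
        stim[(times >= on) & (times < off)] = 1.0
        # motor arrest: activity falls below threshold shortly after onset
        mask = (times >= on + 0.05) & (times < off + 0.3)
        activity[mask] = cfg.inactive_level

    rec = PhysioRecording(
        sample_rate=cfg.sample_rate, flow=flow, ecg=ecg,
        activity=activity, stim=stim,
    )
    truth = GroundTruth(
        breath_times=breath_times,
        beat_times=beat_times,
        apnea_intervals=[tuple(w) for w in windows]
        if cfg.resp_effect == "apnea" else [],
        extra={"stim_windows": [tuple(w) for w in windows],
               "activity_threshold": cfg.activity_threshold},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cylinder / open-field activity sessions
# ---------------------------------------------------------------------------

@dataclass
class CylinderSimConfig:
    """Configuration for a synthetic cylinder/open-field activity session.

    The activity trace follows a behavior template (single-peak ambulation,
    flat grooming, double-peak rearing) around the light window; ChR2-like
    sessions suppress activity to ``suppression_level`` during the light
    epoch, control-like sessions do not. Below-threshold arrest bouts can be
    implanted explicitly via ``arrest_bouts``.
    """

    sample_rate: float = 25.0
    session_duration: float = 30.0
    light_onset: float = 12.0
    epoch_len: float = 3.0
    behavior: str = "ambulation"   # ambulation|grooming|rearing
    chr2_like: bool = True
    suppression_level: float = 0.0
    inactivity_threshold: float = 0.5
    active_level: float = 2.0
    inactive_level: float = 0.05
    noise_sd: float = 0.0
    arrest_bouts: tuple[tuple[float, float], ...] = ()  # (onset, duration) s
    seed: int = 0

    def validate(self) -> None:
        if self.epoch_len <= 0 or self.epoch_len > self.session_duration:
            raise ValueError("epoch length must be positive and fit the session")
        if (self.light_onset - self.epoch_len < 0
                or self.light_onset + 2 * self.epoch_len > self.session_duration):
            raise ValueError("before/light/after epochs must fit the session")
        if self.behavior not in ("ambulation", "grooming", "rearing"):
            raise ValueError(f"unknown behavior template {self.behavior!r}")


@dataclass
class CylinderSession:
    """A generated activity session plus its stimulation annotation."""

    activity: np.ndarray
    sample_rate: float
    light_onset: float
    epoch_len: float
    inactivity_threshold: float
    behavior: str


def gen_cylinder_session(cfg: CylinderSimConfig) -> tuple[CylinderSession, GroundTruth]:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.session_duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate

    activity = np.full(n, cfg.active_level)
    center = cfg.light_onset + cfg.epoch_len / 2
    if cfg.behavior == "ambulation":
        activity += cfg.active_level * 0.5 * np.exp(
            -0.5 * ((t - center) / 1.5) ** 2)
    elif cfg.behavior == "rearing":
        activity += cfg.active_level * 0.5 * (
            np.exp(-0.5 * ((t - (center - 2.0)) / 0.8) ** 2)
            + np.exp(-0.5 * ((t - (center + 2.0)) / 0.8) ** 2))
    # grooming: flat

    if cfg.chr2_like:
        light = (t >= cfg.light_onset) & (t < cfg.light_onset + cfg.epoch_len)
        activity[light] = cfg.suppression_level

    bouts: list[tuple[float, float]] = []
    for onset, duration in cfg.arrest_bouts:
        mask = (t >= onset) & (t < onset + duration)
        activity[mask] = cfg.inactive_level
        bouts.append((onset, onset + duration))

    if cfg.noise_sd > 0:
        activity = np.clip(activity + rng.normal(0, cfg.noise_sd, n), 0, None)

    session = CylinderSession(
        activity=activity, sample_rate=cfg.sample_rate,
        light_onset=cfg.light_onset, epoch_len=cfg.epoch_len,
        inactivity_threshold=cfg.inactivity_threshold, behavior=cfg.behavior,
    )
    truth = GroundTruth(arrest_bouts=bouts,
                        extra={"chr2_like": cfg.chr2_like})
    return session, truth


# ---------------------------------------------------------------------------
# Anesthetized combined recordings (phase-response input)
# ---------------------------------------------------------------------------

@dataclass
class AnesthetizedSimConfig:
    """Configuration for a synthetic anesthetized recording with short
    stimulation trains delivered at random phases of the respiratory period.

    ``perturbation`` is the tabulated perturbation function Delta(phi): the
    fractional period lengthening as a function of normalized stimulus
    phase. A stimulated period obeys ``P = T * (1 + Delta(phi))``. It may be
    a callable or a pair ``(phase_edges, values)`` interpreted as a step
    function (value[i] applies for phase >= phase_edges[i]).
    """

    baseline_period: float = 0.25   # s
    n_cycles: int = 80
    stim_every: int = 5             # one stimulus every k-th period (k >= 3)
    perturbation: object = None     # callable phi -> Delta, or (edges, values)
    heart_rate: float = 600.0       # bpm, independent cardiac train
    jitter: float = 0.0             # fractional sd of unperturbed periods
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_period <= 0:
            raise ValueError("baseline_period must be positive")
        if self.stim_every < 3:
            raise ValueError("stim_every must be >= 3 so neighbors are clean")


def _as_delta_fn(perturbation):
    if perturbation is None:
        return lambda phi: 0.0
    if callable(perturbation):
        return perturbation
    edges, values = perturbation
    edges = np.asarray(edges, dtype=float)
    values = np.asarray(values, dtype=float)

    def fn(phi: float) -> float:
        idx = np.searchsorted(edges, phi, side="right") - 1
        return float(values[max(idx, 0)])

    return fn


def gen_anesthetized_recording(
    cfg: AnesthetizedSimConfig,
) -> tuple[EventSeries, EventSeries, EventSeries, GroundTruth]:
    """Generate respiratory burst onsets, stimulus onsets and a cardiac
    train with a known perturbation function.

    Returns ``(bursts, stims, beats, truth)``; ``truth.extra`` records each
    stimulus' true phase and Delta value.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    delta_fn = _as_delta_fn(cfg.perturbation)

    onsets = [0.5]
    stim_times: list[float] = []
    true_phases: list[float] = []
    true_deltas: list[float] = []
    for j in range(cfg.n_cycles):
        base = cfg.baseline_period
        if cfg.jitter > 0:
            base *= 1.0 + cfg.jitter * rng.standard_normal()
            base = max(base, 0.3 * cfg.baseline_period)
        # stimulate the middle of every k-th block, never the first/last cycle
        if j % cfg.stim_every == cfg.stim_every // 2 and 0 < j < cfg.n_cycles - 1:
            phi = rng.uniform(0.0, 1.0)
            d = delta_fn(phi)
            if d <= -1.0:
                raise ValueError("perturbation Delta must be > -1")
            period = base * (1.0 + d)
            stim_times.append(onsets[-1] + phi * period)
            true_phases.append(phi)
            true_deltas.append(d)
        else:
            period = base
        onsets.append(onsets[-1] + period)

    duration = onsets[-1] + 0.5
    beat_iv = 60.0 / cfg.heart_rate
    beats = np.arange(0.05, duration, beat_iv)

    bursts = EventSeries(np.asarray(onsets), kind="burst")
    stims = EventSeries(np.asarray(stim_times), kind="stim")
    beat_series = EventSeries(beats, kind="beat")
    truth = GroundTruth(
        perturbation=cfg.perturbation,
        extra={"stim_phases": np.asarray(true_phases),
               "stim_deltas": np.asarray(true_deltas),
               "baseline_period": cfg.baseline_period},
    )
    return bursts, stims, beat_series, truth


# ---------------------------------------------------------------------------
# Anatomical spot fields
# ---------------------------------------------------------------------------

def gen_spot_field(
    n_a: int,
    n_b: int,
    area_mm2: float,
    coloc_fraction: float,
    jitter_um: float,
    seed: int,
    radius_um: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate two spot-centroid tables with a known colocalized fraction.

    ``coloc_fraction`` of the type-A spots receive a type-B partner within
    ``jitter_um``; all remaining cross-type pairs are kept at least twice
    the colocalization radius apart so recovery is unambiguous.

    Returns ``(spots_a, spots_b, truth)`` with centroid coordinates in
    micrometers.
    """
    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must lie in [0, 1]")
    if jitter_um < 0:
        raise ValueError("jitter_um must be >= 0")
    if jitter_um >= radius_um:
        raise ValueError("jitter_um must be smaller than the colocalization radius")
    if n_b < int(round(coloc_fraction * n_a)):
        raise ValueError("n_b too small for the requested colocalized fraction")

    rng = np.random.default_rng(seed)
    side = np.sqrt(area_mm2) * 1000.0  # um
    sep = 2.0 * radius_um
    n_coloc = int(round(coloc_fraction * n_a))

    def _place(n_points: int, others: list[np.ndarray], min_d: float) -> np.ndarray:
        pts: list[np.ndarray] = []
        pool = np.concatenate(others) if others else np.empty((0, 2))
        attempts = 0
        while len(pts) < n_points:
            attempts += 1
            if attempts > 400 * max(n_points, 1):
                raise ValueError(
                    "spot density too high for the separation constraint")
            cand = rng.uniform(0, side, 2)
            ok = True
            for arr in (pool, np.asarray(pts) if pts else np.empty((0, 2))):
                if len(arr) and np.min(
                        np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1])) < min_d:
                    ok = False
                    break
            if ok:
                pts.append(cand)
        return np.asarray(pts).reshape(n_points, 2)

    # A spots mutually separated so greedy matching is unambiguous
    spots_a = _place(n_a, [], 3.0 * radius_um)

    partners = []
    for i in range(n_coloc):
        r = rng.uniform(0, jitter_um) if jitter_um > 0 else 0.0
        ang = rng.uniform(0, 2 * np.pi)
        partners.append(spots_a[i] + r * np.array([np.cos(ang), np.sin(ang)]))
    partners_arr = (np.asarray(partners).reshape(n_coloc, 2)
                    if n_coloc else np.empty((0, 2)))

    # unmatched B spots: at least 2x radius from every A spot
    far_b = _place(n_b - n_coloc, [spots_a], sep) if n_b > n_coloc \
        else np.empty((0, 2))
    spots_b = np.concatenate([partners_arr, far_b])
    # shuffle B rows so order carries no information
    spots_b = spots_b[rng.permutation(len(spots_b))]

    truth = GroundTruth(
        coloc_fraction=n_coloc / n_a if n_a else 0.0,
        extra={"n_coloc": n_coloc, "radius_um": radius_um},
    )
    return spots_a, spots_b, truth
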