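"""Core data containers shared across the pipeline.

All times are in seconds, 0-referenced to the start of the recording.
Trial-aligned analyses re-reference to light onset = 0 at the point of use.
Positions are stored internally in meters (SI); limb speeds are reported in
cm/s, matching the conventions of the corridor assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical marker names for a corridor trial: left/right fore paw,
#: left/right hind paw, tail base, trunk midpoint.
MARKERS = ("LF", "RF", "LH", "RH", "B", "M")


@dataclass
class TrackedTrial:
    """Per-frame marker positions for one corridor trial.

    Parameters
    ----------
    positions
        Mapping from marker name to an ``(n_frames, 2)`` array of x, y
        positions in meters.
    frame_rate
        Acquisition frame rate in frames/s.
    light_onset, light_offset
        Stimulation window in seconds from trial start.
    likelihood
        Optional per-marker tracking-confidence arrays in ``[0, 1]``.
    """

    positions: dict[str, np.ndarray]
    frame_rate: float
    light_onset: float
    light_offset: float
    likelihood: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lengths = {len(p) for p in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError("all marker tracks must have equal length")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def x(self, marker: str) -> np.ndarray:
        return self.positions[marker][:, 0]

    def y(self, marker: str) -> np.ndarray:
        return self.positions[marker][:, 1]


@dataclass
class PhysioRecording:
    """Synchronized physiological traces for one session.

    Traces are uniformly sampled at ``sample_rate`` (1 kHz by default in the
    acquisition setup this models). Any of ``flow``/``ecg``/``activity`` may
    be absent. ``stim`` is a 0/1 gate trace; onsets/offsets are recovered
    from its edges.
    """

    sample_rate: float
    flow: np.ndarray | None = None
    ecg: np.ndarray | None = None
    activity: np.ndarray | None = None
    stim: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        for trace in (self.flow, self.ecg, self.activity, self.stim):
            if trace is not None:
                return len(trace)
        return 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def stim_windows(self) -> list[tuple[float, float]]:
        """(onset, offset) pairs, in seconds, from edges of the stim gate."""
        if self.stim is None:
            return []
        gate = np.asarray(self.stim) > 0.5
        d = np.diff(gate.astype(int))
        onsets = np.flatnonzero(d == 1) + 1
        offsets = np.flatnonzero(d == -1) + 1
        if gate[0]:
            onsets = np.r_[0, onsets]
        if gate[-1]:
            offsets = np.r_[offsets, len(gate)]
        return [(on / self.sample_rate, off / self.sample_rate)
                for on, off in zip(onsets, offsets)]


@dataclass
class EventSeries:
    """Ordered event times: breaths (peak inspiratory flow), heartbeats
    (R-waves), respiratory burst onsets, or stimulation onsets."""

    times: np.ndarray
    kind: str = "event"
    source: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ArrestEvent:
    """An immobility/apnea episode with provenance."""

    onset: float
    offset: float
    provenance: str = "evoked"  # "evoked" or "natural"

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class GroundTruth:
    """Known ground truth attached to a synthetic session.

    Every generated observable has a matching truth record, enabling
    parameter-recovery tests downstream.
    """

    arrest_time: float | None = None
    resume_time: float | None = None
    phase_offset_deg: float | None = None
    breath_times: np.ndarray | None = None
    beat_times: np.ndarray | None = None
    apnea_intervals: list[tuple[float, float]] = field(default_factory=list)
    arrest_bouts: list[tuple[float, float]] = field(default_factory=list)
    coloc_fraction: float | None = None
    perturbation: object | None = None
    extra: dict = field(default_factory=dict)
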