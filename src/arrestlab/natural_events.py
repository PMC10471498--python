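"""Naturally occurring apneic-arrest detection in baseline sessions.

An apnea candidate is any inter-breath gap of at least 500 ms (the 500-ms
default corresponds to the empirical 99th percentile of baseline
inter-breath intervals in the assay this models; a helper recomputes the
percentile from user data on request). A candidate becomes an apneic-arrest
event when the animal spent at least 80% of the gap in an inactive state.
Events with gaps longer than 800 ms are flagged ``is_long`` — the subset
comparable in length to 1-s optogenetic stimulations. Putative onsets
("natural triggers") are assigned by subtracting a uniformly distributed
random latency spanning the evoked latency-to-arrest mean +/- s.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activitystate import ActivityTrace
from .datatypes import EventSeries

__all__ = [
    "ApneicArrestEvent",
    "detect_apneic_arrests",
    "assign_putative_onsets",
    "apnea_gap_percentile",
]

MIN_GAP_S = 0.5
LONG_GAP_S = 0.8
MIN_INACTIVE_FRACTION = 0.8

#: Evoked latency-to-arrest summary (s) used for putative-onset assignment.
DEFAULT_LATENCY_MEAN = 0.11083
DEFAULT_LATENCY_SD = 0.04401


@dataclass
class ApneicArrestEvent:
    """One naturally occurring apneic arrest.

    ``apnea_onset`` is the last breath before the gap, ``apnea_offset``
    the first breath after it.
    """

    apnea_onset: float
    apnea_offset: float
    inactive_fraction: float
    putative_onset: float | None = None
    onset_clipped: bool = False

    @property
    def gap(self) -> float:
        return self.apnea_offset - self.apnea_onset

    @property
    def is_long(self) -> bool:
        return self.gap > LONG_GAP_S


def detect_apneic_arrests(
    breaths: EventSeries,
    activity: ActivityTrace,
    min_gap_s: float = MIN_GAP_S,
    min_inactive_fraction: float = MIN_INACTIVE_FRACTION,
) -> list[ApneicArrestEvent]:
    """Detect apneic arrests from a breath series and a co-registered
    activity trace.

    Every inter-breath gap of at least ``min_gap_s`` is a candidate; the
    fraction of activity samples at or below the inactivity threshold
    within [onset, offset] must reach ``min_inactive_fraction``.
    """
    times = breaths.times
    if len(times) < 2:
        return []
    t_act = activity.times
    inactive = ~activity.active_mask()
    events: list[ApneicArrestEvent] = []
    gaps = np.diff(times)
    for i in np.flatnonzero(gaps >= min_gap_s):
        onset, offset = float(times[i]), float(times[i + 1])
        mask = (t_act >= onset) & (t_act <= offset)
        if not mask.any():
            continue
        frac = float(np.mean(inactive[mask]))
        if frac >= min_inactive_fraction:
            events.append(ApneicArrestEvent(
                apnea_onset=onset, apnea_offset=offset,
                inactive_fraction=frac))
    return events


def assign_putative_onsets(
    events: list[ApneicArrestEvent],
    latency_mean: float = DEFAULT_LATENCY_MEAN,
    latency_sd: float = DEFAULT_LATENCY_SD,
    seed: int | None = None,
) -> list[ApneicArrestEvent]:
    """Assign putative trigger onsets by subtracting random latencies.

    Latencies are drawn uniformly from
    ``[latency_mean - latency_sd, latency_mean + latency_sd]``. A putative
    onset that would fall before the recording start is clipped to 0 and
    flagged. Events are modified in place and returned.
    """
    if not (latency_mean > latency_sd >= 0):
        raise ValueError("require latency_mean > latency_sd >= 0")
    rng = np.random.default_rng(seed)
    for ev in events:
        lat = rng.uniform(latency_mean - latency_sd, latency_mean + latency_sd)
        onset = ev.apnea_onset - lat
        ev.onset_clipped = onset < 0
        ev.putative_onset = max(onset, 0.0)
    return events


def apnea_gap_percentile(breaths: EventSeries, q: float = 99.0) -> float:
    """Recompute the apnea gap threshold as the ``q``-th percentile of the
    inter-breath intervals of a baseline recording."""
    if len(breaths) < 2:
        raise ValueError("need at least two breaths")
    return float(np.percentile(np.diff(breaths.times), q))
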