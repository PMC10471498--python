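"""Pixel-change activity analysis: active/inactive classification, epoch
percentages, arrest-bout counting, ablation comparison, and chamber
preference.

The activity metric is the percentage of arena pixels that changed between
consecutive video samples, ``activity = 100 * CP_n / P_n``. A sample is
"active" when its activity is strictly above the inactivity threshold;
samples exactly at the threshold count as inactive. The threshold itself is
setup-specific (it depends on resolution and subject size) and is mandatory
configuration with no claimed-faithful default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivityTrace",
    "ArrestBout",
    "compute_activity",
    "percent_time_active",
    "count_arrest_bouts",
    "percent_change_from_baseline",
    "chamber_preference",
]


@dataclass
class ActivityTrace:
    """Percent-pixels-changed activity trace with its classification
    threshold."""

    activity: np.ndarray       # %
    sample_rate: float         # Hz
    inactivity_threshold: float  # %

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.activity)) / self.sample_rate

    def active_mask(self) -> np.ndarray:
        """Strictly-above-threshold classification per sample."""
        return self.activity > self.inactivity_threshold


@dataclass
class ArrestBout:
    """A maximal below-threshold run."""

    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def qualifies(self) -> bool:
        """True for bouts between 500 ms and 2 s (inclusive), the window
        that avoids confusion with longer freezing-like immobility."""
        return 0.5 <= self.duration <= 2.0


def compute_activity(
    frame_diff_counts: np.ndarray,
    total_pixels: int,
    sample_rate: float,
    inactivity_threshold: float,
) -> ActivityTrace:
    """Percent of pixels changed per sample from precomputed changed-pixel
    counts."""
    counts = np.asarray(frame_diff_counts, dtype=float)
    if total_pixels <= 0:
        raise ValueError("total_pixels must be positive")
    if np.any(counts < 0) or np.any(counts > total_pixels):
        raise ValueError("changed-pixel counts must lie in [0, total_pixels]")
    return ActivityTrace(
        activity=100.0 * counts / total_pixels,
        sample_rate=sample_rate,
        inactivity_threshold=inactivity_threshold,
    )


def percent_time_active(
    trace: ActivityTrace,
    light_onset: float,
    epoch_len: float = 3.0,
) -> dict[str, float]:
    """Percent of samples strictly above threshold in each of the three
    equal epochs (before, light_on, after) around the light window.

    Raises if the trace does not cover all three epochs.
    """
    t = trace.times
    active = trace.active_mask()
    edges = {
        "before": (light_onset - epoch_len, light_onset),
        "light_on": (light_onset, light_onset + epoch_len),
        "after": (light_onset + epoch_len, light_onset + 2 * epoch_len),
    }
    out: dict[str, float] = {}
    dt = 1.0 / trace.sample_rate
    for name, (lo, hi) in edges.items():
        if lo < t[0] - 1e-9 or hi > t[-1] + dt + 1e-9:
            raise ValueError(f"trace does not cover the {name!r} epoch")
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError(f"no samples in the {name!r} epoch")
        out[name] = 100.0 * float(np.mean(active[mask]))
    return out


def count_arrest_bouts(trace: ActivityTrace) -> tuple[list[ArrestBout], int]:
    """Segment maximal below-threshold runs and count qualifying bouts
    (0.5 s <= duration <= 2 s)."""
    inactive = ~trace.active_mask()
    bouts: list[ArrestBout] = []
    n = len(inactive)
    dt = 1.0 / trace.sample_rate
    k = 0
    while k < n:
        if inactive[k]:
            stop = k
            while stop < n and inactive[stop]:
                stop += 1
            bouts.append(ArrestBout(onset=k * dt, offset=stop * dt))
            k = stop
        else:
            k += 1
    return bouts, sum(b.qualifies for b in bouts)


def percent_change_from_baseline(
    baseline_counts: tuple[float, float],
    post_count: float,
) -> float:
    """Percent change of a post-session bout count from the mean of two
    baseline sessions."""
    base = float(np.mean(baseline_counts))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (post_count - base) / base


@dataclass
class ChamberPreference:
    percent_left: float
    percent_right: float
    percent_excluded: float   # samples in neither chamber, of all samples
    preferred: str | None     # "left" | "right" | None on an exact tie


def chamber_preference(
    x: np.ndarray,
    divider_x: float,
    left_range: tuple[float, float] | None = None,
    right_range: tuple[float, float] | None = None,
) -> ChamberPreference:
    """Percent of tracked time in each of two chambers split at
    ``divider_x``.

    Samples outside both chambers (e.g. in a connecting doorway region if
    explicit ranges are given) are excluded from the percentages and
    reported. The preferred side is the one holding > 50% of in-chamber
    time; an exact 50/50 tie yields ``preferred=None`` and is left to the
    analyst.
    """
    x = np.asarray(x, dtype=float)
    if left_range is None:
        in_left = x < divider_x
    else:
        in_left = (x >= left_range[0]) & (x < left_range[1])
    if right_range is None:
        in_right = x >= divider_x
    else:
        in_right = (x >= right_range[0]) & (x < right_range[1])
    n_left, n_right = int(in_left.sum()), int(in_right.sum())
    n_in = n_left + n_right
    if n_in == 0:
        raise ValueError("no samples fall inside either chamber")
    pl = 100.0 * n_left / n_in
    pr = 100.0 * n_right / n_in
    preferred = "left" if pl > 50.0 else "right" if pr > 50.0 else None
    return ChamberPreference(
        percent_left=pl,
        percent_right=pr,
        percent_excluded=100.0 * (len(x) - n_in) / len(x),
        preferred=preferred,
    )
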