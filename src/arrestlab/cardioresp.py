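"""Physiological signal preprocessing, event detection and trial-aligned
rate analysis.

Breaths are detected as peak inspiratory flow (PIF) events on the
plethysmograph flow trace (inspiration is a downward deflection, so the
trace is inverted before peak finding); heartbeats as R-waves on the ECG.
Rates are analysed trial-aligned in 100-ms bins: rasters and peri-stimulus
time histograms, per-mouse maximum rate change from a 5-s pre-onset
baseline, baseline z-scores, and unsmoothed epoch averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .datatypes import EventSeries

__all__ = [
    "RateSeries",
    "MaxChangeResult",
    "preprocess_trace",
    "detect_events",
    "align_events",
    "build_psth",
    "mean_rate_series",
    "max_rate_change",
    "rate_zscore",
    "epoch_rate_averages",
]

#: Centered moving-average windows (s) for signal cleaning.
SMOOTH_WINDOWS_S = {"ecg": 0.003, "flow": 0.021}

#: Minimum inter-event distances (s): breaths capped at 10 Hz, beats at
#: 1000 bpm.
MIN_DISTANCE_S = {"breath": 0.1, "beat": 0.06}

PSTH_BIN_WIDTH = 0.1    # s
RATE_SMOOTH_BINS = 3    # 300-ms centered moving average


@dataclass
class RateSeries:
    """Binned event rate aligned to light onset (onset = 0).

    ``rate[k]`` is the mean rate in ``[edges[k], edges[k+1])``; events
    falling exactly on an edge belong to the later bin.
    """

    edges: np.ndarray       # s, bin edges, onset-anchored
    rate: np.ndarray        # Hz (breaths) or bpm (beats)
    counts: np.ndarray      # pooled event counts per bin
    n_trials: int
    bin_width: float
    unit: str               # "Hz" | "bpm"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class MaxChangeResult:
    """Maximum rate change during the stimulus search window, as percent
    of the 5-s pre-onset baseline."""

    baseline_rate: float
    min_rate: float
    change: float      # signed %, negative for a drop
    magnitude: float   # |change|


def preprocess_trace(
    raw: np.ndarray,
    kind: str,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Clean a raw physiological trace: centered moving average (3 ms for
    ECG, 21 ms for flow) followed by offset removal (subtract the mean of
    the whole recording)."""
    if kind not in SMOOTH_WINDOWS_S:
        raise ValueError(f"kind must be one of {sorted(SMOOTH_WINDOWS_S)}")
    raw = np.asarray(raw, dtype=float)
    w = max(int(round(SMOOTH_WINDOWS_S[kind] * sample_rate)), 1)
    if len(raw) < w:
        raise ValueError("trace shorter than the smoothing window")
    smoothed = uniform_filter1d(raw, size=w, mode="nearest")
    return smoothed - smoothed.mean()


def detect_events(
    cleaned: np.ndarray,
    kind: str,
    sample_rate: float = 1000.0,
    height: float | None = None,
    prominence: float | None = None,
    distance_s: float | None = None,
    width_s: float | None = None,
) -> EventSeries:
    """Detect breath (PIF) or beat (R-wave) events as local maxima.

    The flow trace is inverted internally so PIFs appear as maxima. Unless
    given, the peak-property thresholds are derived from the trace itself
    (prominence: 4x the median absolute deviation; height: 20% of the
    99.5th percentile of the signal magnitude), so rescaling the trace
    leaves the detected event times unchanged. An empty series is a valid
    result.
    """
    if kind not in ("breath", "beat"):
        raise ValueError("kind must be 'breath' or 'beat'")
    x = np.asarray(cleaned, dtype=float)
    if kind == "breath":
        x = -x  # inspiration is negative flow; PIFs become maxima
    if prominence is None:
        mad = float(np.median(np.abs(x - np.median(x))))
        prominence = 4.0 * mad
    if height is None:
        height = 0.2 * float(np.quantile(np.abs(x), 0.995))
    if distance_s is None:
        distance_s = MIN_DISTANCE_S[kind]
    kw: dict = {
        "height": height if height > 0 else None,
        "prominence": prominence if prominence > 0 else None,
        "distance": max(int(round(distance_s * sample_rate)), 1),
    }
    if width_s is not None:
        kw["width"] = width_s * sample_rate
    idx, _ = find_peaks(x, **{k: v for k, v in kw.items() if v is not None})
    return EventSeries(times=idx / sample_rate, kind=kind)


def align_events(
    events: EventSeries,
    onsets: np.ndarray,
    pre: float,
    post_from_onset: float,
) -> list[np.ndarray]:
    """Per-trial event times relative to each stimulation onset (raster)."""
    out = []
    for on in np.asarray(onsets, dtype=float):
        rel = events.times - on
        out.append(rel[(rel >= -pre) & (rel < post_from_onset)])
    return out


def _bin_trials(
    trials: list[np.ndarray],
    pre: float,
    post: float,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled counts in onset-anchored bins spanning [-pre, post)."""
    n_pre = int(round(pre / bin_width))
    n_post = int(round(post / bin_width))
    edges = (np.arange(-n_pre, n_post + 1) * bin_width)
    counts = np.zeros(len(edges) - 1)
    for rel in trials:
        rel = np.asarray(rel, dtype=float)
        # half-open bins [e_k, e_k+1): an event on an edge joins the later
        # bin; events at/after the final edge are outside the window
        k = np.floor((rel + n_pre * bin_width) / bin_width + 1e-12).astype(int)
        k = k[(k >= 0) & (k < len(counts))]
        np.add.at(counts, k, 1)
    return edges, counts


def build_psth(
    trials: list[np.ndarray],
    stim_duration: float,
    unit: str = "Hz",
    pre: float = 3.0,
    post: float = 3.0,
    bin_width: float = PSTH_BIN_WIDTH,
) -> RateSeries:
    """Mean event rate per 100-ms bin across trials, in a window holding
    the whole stimulus plus ``pre`` seconds before and ``post`` after.

    ``trials`` holds per-trial event times relative to light onset.
    """
    if len(trials) == 0:
        raise ValueError("at least one trial is required")
    edges, counts = _bin_trials(trials, pre, stim_duration + post, bin_width)
    rate = counts / len(trials) / bin_width
    if unit == "bpm":
        rate = rate * 60.0
    elif unit != "Hz":
        raise ValueError("unit must be 'Hz' or 'bpm'")
    return RateSeries(edges=edges, rate=rate, counts=counts,
                      n_trials=len(trials), bin_width=bin_width, unit=unit)


def mean_rate_series(
    trials: list[np.ndarray],
    stim_duration: float,
    unit: str = "Hz",
    pre: float = 5.0,
    post: float = 5.0,
    bin_width: float = PSTH_BIN_WIDTH,
) -> RateSeries:
    """Continuous per-mouse mean rate: PSTH binning over a 5-s pre / 5-s
    post window (the window used by maximum-change, z-score and epoch
    analyses)."""
    return build_psth(trials, stim_duration, unit=unit, pre=pre, post=post,
                      bin_width=bin_width)


def smooth_rate(rate: np.ndarray, bins: int = RATE_SMOOTH_BINS) -> np.ndarray:
    """Centered moving average over ``bins`` bins (300 ms by default)."""
    return uniform_filter1d(np.asarray(rate, dtype=float), size=bins,
                            mode="nearest")


def max_rate_change(
    mouse_rate: RateSeries,
    stim_duration: float,
    baseline_s: float = 5.0,
    search_pad: float = 0.5,
    smooth_bins: int = RATE_SMOOTH_BINS,
) -> MaxChangeResult:
    """Maximum rate change relative to the pre-onset baseline.

    The per-mouse mean rate is smoothed (300-ms centered moving average),
    the baseline is the mean over the 5 s before light onset (= 100%), and
    the extreme is the minimum over the light-on period plus 500 ms after
    light offset -- the padding accommodates the slow cardiac dynamics
    where the maximal drop lands at or just after the end of the stimulus.
    """
    centers = mouse_rate.centers
    smoothed = smooth_rate(mouse_rate.rate, smooth_bins)
    base_mask = (centers >= -baseline_s) & (centers < 0.0)
    if not base_mask.any() or centers[0] > -baseline_s + mouse_rate.bin_width:
        raise ValueError("rate series must cover the 5-s pre-onset baseline")
    baseline = float(smoothed[base_mask].mean())
    if baseline == 0.0:
        raise ValueError("zero baseline rate; maximum change undefined")
    search = (centers >= 0.0) & (centers < stim_duration + search_pad)
    if not search.any():
        raise ValueError("rate series does not cover the search window")
    min_rate = float(smoothed[search].min())
    change = 100.0 * (min_rate - baseline) / baseline
    return MaxChangeResult(baseline_rate=baseline, min_rate=min_rate,
                           change=change, magnitude=abs(change))


def rate_zscore(
    mouse_rate: RateSeries,
    baseline_s: float = 5.0,
    smooth_bins: int = RATE_SMOOTH_BINS,
) -> np.ndarray:
    """Per-bin z-score of the mouse mean rate against its own 5-s
    pre-onset baseline, smoothed with a 300-ms centered moving average.

    A constant trace (zero baseline s.d. with no deviations anywhere)
    yields all-zero z-scores; a zero baseline s.d. with non-baseline
    deviations is undefined and raises.
    """
    centers = mouse_rate.centers
    base_mask = (centers >= -baseline_s) & (centers < 0.0)
    if not base_mask.any():
        raise ValueError("rate series must cover the pre-onset baseline")
    mu = float(mouse_rate.rate[base_mask].mean())
    sd = float(mouse_rate.rate[base_mask].std())
    if sd == 0.0:
        if np.allclose(mouse_rate.rate, mu):
            return np.zeros_like(mouse_rate.rate)
        raise ValueError("zero baseline s.d.; z-scores undefined")
    return smooth_rate((mouse_rate.rate - mu) / sd, smooth_bins)


def epoch_rate_averages(
    mouse_rate: RateSeries,
    stim_duration: float,
    epoch_s: float = 5.0,
) -> dict[str, float]:
    """Unsmoothed mean rates in the before (5 s), light-on and after (5 s)
    epochs of the per-mouse mean rate."""
    centers = mouse_rate.centers
    w = mouse_rate.bin_width
    spans = {
        "before": (-epoch_s, 0.0),
        "light_on": (0.0, stim_duration),
        "after": (stim_duration, stim_duration + epoch_s),
    }
    out: dict[str, float] = {}
    for name, (lo, hi) in spans.items():
        mask = (centers >= lo) & (centers < hi)
        if not mask.any() or centers[0] > lo + w or centers[-1] < hi - w:
            raise ValueError(f"rate series does not cover the {name!r} epoch")
        out[name] = float(mouse_rate.rate[mask].mean())
    return out
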