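"""Respiratory phase-response analysis for short stimulation trains.

The respiratory period ``P`` is the time between two consecutive
inspiratory burst onsets. For each stimulus delivered inside a period, the
phase-shift statistic is ``R = P / (P_-1 + P_+1)``, the perturbed period
divided by the sum of its flanking periods. With similar periods all
around, ``R`` sits near 0.5 ("unaffected", extended to the band
[0.4, 0.6] to absorb ordinary cycle-to-cycle variability); a prolonged
perturbed period pushes ``R`` into (0.6, 1.0] ("perturbed"), whether the
underlying mechanism is a phase advance with rhythm resetting or a phase
delay without resetting — the statistic does not distinguish the two.
Values outside both bands are flagged "other".

On the normalized period axis the inspiratory phase extends approximately
over [0, 0.3) and the expiratory phase over [0.3, 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RespiratoryCycle",
    "RespiratoryCycleSet",
    "PRCPoint",
    "segment_cycles",
    "compute_R",
    "classify_perturbation",
    "build_prc",
    "burst_offsets_by_threshold",
]

UNAFFECTED_BAND = (0.4, 0.6)   # inclusive on both edges
PERTURBED_BAND = (0.6, 1.0)    # (0.6, 1.0], tie at 0.6 goes to unaffected

#: Approximate inspiratory/expiratory split on the normalized period.
INSPIRATORY_PHASE_END = 0.3


@dataclass
class RespiratoryCycle:
    """One stimulated respiratory cycle with its flanking periods."""

    stim_time: float
    onset: float        # burst onset opening the perturbed period
    period: float       # P
    period_before: float  # P_-1
    period_after: float   # P_+1
    stim_phase: float   # (stim_time - onset) / P, in [0, 1)

    @property
    def R(self) -> float:
        return compute_R(self.period, self.period_before, self.period_after)


@dataclass
class RespiratoryCycleSet:
    cycles: list[RespiratoryCycle] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class PRCPoint:
    stim_phase: float
    R: float
    label: str  # "unaffected" | "perturbed" | "other"


def segment_cycles(
    burst_onsets: np.ndarray,
    stim_onsets: np.ndarray,
) -> RespiratoryCycleSet:
    """Map each stimulus to its containing respiratory period.

    A stimulus is kept only when its period has complete neighbors on both
    sides (a bracketing onset triplet); others are counted in
    ``n_skipped``.
    """
    onsets = np.asarray(burst_onsets, dtype=float)
    out = RespiratoryCycleSet()
    for t_stim in np.asarray(stim_onsets, dtype=float):
        j = int(np.searchsorted(onsets, t_stim, side="right")) - 1
        # need onsets j-1, j, j+1, j+2 for P_-1, P, P_+1
        if j < 1 or j + 2 >= len(onsets):
            out.n_skipped += 1
            continue
        p = onsets[j + 1] - onsets[j]
        p_m1 = onsets[j] - onsets[j - 1]
        p_p1 = onsets[j + 2] - onsets[j + 1]
        if min(p, p_m1, p_p1) <= 0:
            out.n_skipped += 1
            continue
        out.cycles.append(RespiratoryCycle(
            stim_time=float(t_stim),
            onset=float(onsets[j]),
            period=float(p),
            period_before=float(p_m1),
            period_after=float(p_p1),
            stim_phase=float((t_stim - onsets[j]) / p),
        ))
    return out


def compute_R(p: float, p_minus1: float, p_plus1: float) -> float:
    """Phase-shift statistic R = P / (P_-1 + P_+1)."""
    if min(p, p_minus1, p_plus1) <= 0:
        raise ValueError("all periods must be positive")
    return p / (p_minus1 + p_plus1)


def classify_perturbation(r: float) -> str:
    """Band classification of R: [0.4, 0.6] unaffected, (0.6, 1.0]
    perturbed, anything else flagged as other."""
    if UNAFFECTED_BAND[0] <= r <= UNAFFECTED_BAND[1]:
        return "unaffected"
    if PERTURBED_BAND[0] < r <= PERTURBED_BAND[1]:
        return "perturbed"
    return "other"


def build_prc(cycles: RespiratoryCycleSet) -> list[PRCPoint]:
    """Phase-response curve: (stimulus phase, R, band label) per stimulus,
    sorted by phase."""
    pts = [PRCPoint(stim_phase=c.stim_phase, R=c.R,
                    label=classify_perturbation(c.R))
           for c in cycles.cycles]
    return sorted(pts, key=lambda p: p.stim_phase)


def burst_offsets_by_threshold(
    trace: np.ndarray,
    burst_onsets: np.ndarray,
    sample_rate: float,
    fraction: float = 0.2,
) -> np.ndarray:
    """Burst offsets as the first post-peak crossing below ``fraction`` of
    the burst peak (used to delimit the expiratory phase, which runs from
    a burst's offset to the next burst's onset)."""
    x = np.asarray(trace, dtype=float)
    onsets = np.asarray(burst_onsets, dtype=float)
    offsets = []
    for i, on in enumerate(onsets):
        start = int(round(on * sample_rate))
        stop = int(round(onsets[i + 1] * sample_rate)) if i + 1 < len(onsets) \
            else len(x)
        seg = x[start:stop]
        if len(seg) == 0:
            offsets.append(on)
            continue
        pk = int(np.argmax(seg))
        below = np.flatnonzero(seg[pk:] < fraction * seg[pk])
        k = pk + (int(below[0]) if len(below) else len(seg) - 1 - pk)
        offsets.append((start + k) / sample_rate)
    return np.asarray(offsets)
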