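"""Anatomical quantification: cell densities, object-based colocalization
and projection (bouton) densities.

Colocalization is object-based: two spot populations (centroids in
micrometers, same coordinate frame) are matched one-to-one, greedily by
ascending centroid distance, with a strict distance criterion
(< 5 um by default). Greedy one-to-one matching prevents a single spot
from being counted twice when several candidates fall inside the radius.

Projection quantification aggregates counts and areas across section
levels first and divides afterwards, then min-max normalizes the per-ROI
bouton density within each animal; ROIs at the injection site (and its
contralateral mirror) are excluded from the normalization but reported on
the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ColocalizationResult",
    "cell_density",
    "colocalize_spots",
    "aggregate_roi_counts",
    "normalize_bouton_density",
    "output_fraction",
]

COLOC_RADIUS_UM = 5.0


def cell_density(count: float, area_mm2: float) -> float:
    """Cell (or bouton) density in counts per mm^2."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area_mm2


@dataclass
class ColocalizationResult:
    """One-to-one spot matches and both directional percentages."""

    matches: list[tuple[int, int]]   # (index in A, index in B)
    n_a: int
    n_b: int

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    @property
    def percent_a_in_b(self) -> float:
        """Percent of A spots with a B partner."""
        return 100.0 * self.n_matched / self.n_a if self.n_a else 0.0

    @property
    def percent_b_in_a(self) -> float:
        """Percent of B spots with an A partner."""
        return 100.0 * self.n_matched / self.n_b if self.n_b else 0.0


def colocalize_spots(
    spots_a: np.ndarray,
    spots_b: np.ndarray,
    radius_um: float = COLOC_RADIUS_UM,
) -> ColocalizationResult:
    """Object-based colocalization by centroid distance.

    A pair is colocalized when the centroid distance is strictly smaller
    than ``radius_um``. Candidate pairs are matched greedily by ascending
    distance, each spot used at most once.
    """
    a = np.atleast_2d(np.asarray(spots_a, dtype=float))
    b = np.atleast_2d(np.asarray(spots_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        return ColocalizationResult(matches=[], n_a=len(a), n_b=len(b))
    tree = cKDTree(b)
    pairs = []
    for i, row in enumerate(a):
        for j in tree.query_ball_point(row, r=radius_um):
            d = float(np.hypot(*(row - b[j])))
            if d < radius_um:  # strict
                pairs.append((d, i, j))
    pairs.sort(key=lambda p: p[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return ColocalizationResult(matches=matches, n_a=len(a), n_b=len(b))


def aggregate_roi_counts(
    levels: list[dict],
) -> dict[str, dict[str, float]]:
    """Sum counts and areas per ROI across section levels, then compute
    densities.

    ``levels`` holds per-level records ``{"roi": str, "count": int,
    "area_mm2": float}``; ROIs are aggregated by name (counts and areas
    summed first, density computed from the sums).
    """
    agg: dict[str, dict[str, float]] = {}
    for rec in levels:
        roi = rec["roi"]
        entry = agg.setdefault(roi, {"count": 0.0, "area_mm2": 0.0})
        entry["count"] += rec["count"]
        entry["area_mm2"] += rec["area_mm2"]
    for roi, entry in agg.items():
        entry["density"] = cell_density(entry["count"], entry["area_mm2"])
    return agg


def normalize_bouton_density(
    densities: dict[str, float],
    exclude: tuple[str, ...] = ("PPN_ipsi", "PPN_contra"),
) -> dict[str, float]:
    """Min-max normalize per-ROI densities within one animal to [0, 1].

    Excluded ROIs (the injection site and its contralateral mirror) do not
    participate in determining the scale but are reported with the same
    animal's scaling applied, so their values are comparable to the rest
    (and may fall outside [0, 1]).
    """
    included = {k: v for k, v in densities.items() if k not in exclude}
    if len(included) < 2:
        raise ValueError("need at least two non-excluded ROIs")
    vals = np.array(list(included.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("all non-excluded densities equal; scale undefined")
    return {k: (v - lo) / (hi - lo) for k, v in densities.items()}


def output_fraction(
    roi_counts: dict[str, float],
    exclude: tuple[str, ...] = ("PPN_ipsi", "PPN_contra"),
) -> dict[str, float]:
    """Fraction of output per ROI: bouton count over the total bouton count
    across all non-excluded ROIs of the animal. Fractions sum to 1 over
    the non-excluded ROIs."""
    included = {k: v for k, v in roi_counts.items() if k not in exclude}
    total = float(sum(included.values()))
    if total <= 0:
        raise ValueError("total bouton count must be positive")
    return {k: v / total for k, v in included.items()}
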