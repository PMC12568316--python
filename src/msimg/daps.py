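"""Density-Aware Peak Selection: greedy maximum-coverage choice of patch centers.

Candidate peaks from every training sample are pooled into one point set on
the (scan, m/z-bin) plane.  A patch of size h×w "covers" the circle of
radius r = sqrt((h/2)² + (w/2)²) around its center — center to diagonal
corner.  DAPS repeatedly scores every still-available point by how many
available points (itself included) fall inside its circle, picks the best
one, and retires everything it covers, until the best score drops below
``tau_min_peaks``.  The result is an ordered list of mutually non-overlapping
patch centers that together cover as much of the pooled signal as a greedy
strategy can.

Scoring uses a k-d tree (``scipy.spatial.cKDTree``) for the radius queries;
because the radius is fixed, neighbor lists are computed once and coverage
counts are maintained incrementally as points retire, which is equivalent to
re-scoring every available point each round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .density import PeakPoint

__all__ = ["CandidatePool", "DapsConfig", "SelectedCenters", "coverage_radius", "score_point", "daps_select"]


def coverage_radius(patch_height: int, patch_width: int) -> float:
    """Distance from a patch center to its diagonal corner: sqrt((h/2)²+(w/2)²)."""
    if patch_height <= 0 or patch_width <= 0:
        raise ValueError("patch dimensions must be positive")
    return math.hypot(patch_height / 2.0, patch_width / 2.0)


@dataclass(frozen=True)
class DapsConfig:
    """Patch geometry and stopping threshold for the greedy selection."""

    patch_height: int = 224
    patch_width: int = 224
    tau_min_peaks: int = 2

    @property
    def radius_r(self) -> float:
        return coverage_radius(self.patch_height, self.patch_width)


class CandidatePool:
    """Pooled per-sample candidate peaks with availability flags and a k-d tree.

    Availability only ever transitions available → unavailable; the point set
    itself is immutable after construction.  Duplicate coordinates (the same
    hotspot found in several samples) are kept — coverage counts points, and
    multiplicity is exactly what makes a shared hotspot score highly.
    """

    def __init__(self, points: Iterable[PeakPoint]):
        self.points: list[PeakPoint] = list(points)
        if not self.points:
            raise ValueError("candidate pool must not be empty")
        self.coords = np.array([(p.row, p.col) for p in self.points], dtype=np.float64)
        self.available = np.ones(len(self.points), dtype=bool)
        self.tree = cKDTree(self.coords)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_available(self) -> int:
        return int(self.available.sum())

    def mark_covered(self, index: int, radius: float) -> np.ndarray:
        """Retire every available point within ``radius`` of point ``index``."""
        hit = np.array(self.tree.query_ball_point(self.coords[index], radius), dtype=np.intp)
        newly = hit[self.available[hit]]
        self.available[newly] = False
        return newly


@dataclass
class SelectedCenters:
    """DAPS output: centers in selection order with their coverage scores."""

    centers: list[tuple[int, int]] = field(default_factory=list)
    scores: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.centers)


def score_point(pool: CandidatePool, index: int, radius_r: float) -> int:
    """Coverage score of an available point: available neighbors within r, itself included."""
    if not pool.available[index]:
        raise ValueError(f"point {index} is no longer available")
    hit = np.asarray(pool.tree.query_ball_point(pool.coords[index], radius_r), dtype=np.intp)
    return int(pool.available[hit].sum())


def daps_select(pool: CandidatePool, config: DapsConfig) -> SelectedCenters:
    """Run the greedy maximum-coverage selection over the pooled candidates.

    Each round selects the available point with the highest coverage score;
    ties break toward the smallest row, then the smallest column.  Selected
    points and everything inside their coverage circle become unavailable, so
    any two returned centers are more than ``radius_r`` apart.  Terminates
    when the best score falls below ``tau_min_peaks`` (possibly immediately).
    """
    r = config.radius_r
    n = len(pool)
    neighbor_lists = pool.tree.query_ball_point(pool.coords, r)
    scores = np.array([len(nb) for nb in neighbor_lists], dtype=np.int64)
    # lexicographic (row, col, pool index) rank used for deterministic tie-breaks
    order = np.lexsort((np.arange(n), pool.coords[:, 1], pool.coords[:, 0]))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    out = SelectedCenters()
    while pool.n_available:
        avail_idx = np.flatnonzero(pool.available)
        avail_scores = scores[avail_idx]
        best_score = int(avail_scores.max())
        if best_score < config.tau_min_peaks:
            break
        contenders = avail_idx[avail_scores == best_score]
        best = int(contenders[np.argmin(rank[contenders])])
        out.centers.append((int(pool.coords[best, 0]), int(pool.coords[best, 1])))
        out.scores.append(best_score)
        retired = pool.mark_covered(best, r)
        # retiring a point removes it from every neighbor's coverage count
        for j in retired:
            scores[neighbor_lists[j]] -= 1
    return out


def pool_from_samples(per_sample_peaks: Sequence[Sequence[PeakPoint]]) -> CandidatePool:
    """Aggregate per-sample NMS peaks into the global candidate pool."""
    return CandidatePool(p for peaks in per_sample_peaks for p in peaks)
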