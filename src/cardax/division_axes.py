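"""Sister-nucleus pairing at cytokinetic bridges and division-axis extraction.

A cytokinetic bridge (Aurkb-positive midbody) connects two sister cells at
the end of division.  Each detected bridge is matched to one nucleus near
each of its two endpoints by a geometric score combining (i) the distances
from the endpoints to the candidate nucleus centroids and (ii) the angle
between the bridge axis and the candidate centroid-joining axis:

    score = (d_i + d_j) / d_max + λ_angle · (1 − |cos θ|)

The minimum-score pair per bridge wins; pairs above a score ceiling are
discarded, and nuclei are consumed greedily in ascending score order so each
nucleus is used at most once.  The division axis is the sign-normalized unit
vector joining the two sister centroids, positioned at their midpoint.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np

from .io_formats import AxisSet, sign_normalize
from .segmentation import LabelMap, SegmentedObject

logger = logging.getLogger("cardax")

__all__ = [
    "Bridge",
    "DivisionAxis",
    "axis_from_pair",
    "pair_sisters",
    "bridges_from_labelmap",
    "axes_to_axis_set",
]


@dataclass(frozen=True)
class Bridge:
    """A cytokinetic bridge: two endpoints (xyz μm) and their unit axis."""

    bridge_id: int
    endpoint_1: np.ndarray
    endpoint_2: np.ndarray

    def __post_init__(self) -> None:
        e1 = np.asarray(self.endpoint_1, dtype=float)
        e2 = np.asarray(self.endpoint_2, dtype=float)
        if np.allclose(e1, e2):
            raise ValueError("bridge endpoints must be distinct")
        object.__setattr__(self, "endpoint_1", e1)
        object.__setattr__(self, "endpoint_2", e2)

    @property
    def axis(self) -> np.ndarray:
        d = self.endpoint_2 - self.endpoint_1
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class DivisionAxis:
    """A division axis joining two sister-nucleus centroids."""

    centroid_1: np.ndarray
    centroid_2: np.ndarray
    axis: np.ndarray  # unit, sign-normalized
    midpoint: np.ndarray
    bridge_id: int = -1
    score: float = 0.0


def axis_from_pair(
    c1: np.ndarray, c2: np.ndarray, bridge_id: int = -1, score: float = 0.0
) -> DivisionAxis:
    """Division axis from two sister centroids (must be distinct)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    d = c2 - c1
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("coincident centroids define no axis")
    return DivisionAxis(
        centroid_1=c1,
        centroid_2=c2,
        axis=sign_normalize(d / norm),
        midpoint=0.5 * (c1 + c2),
        bridge_id=bridge_id,
        score=score,
    )


def pair_sisters(
    bridges: list[Bridge],
    nuclei: list[SegmentedObject],
    lambda_angle: float = 1.0,
    d_max: float = 15.0,
    score_ceiling: float = 2.5,
) -> list[DivisionAxis]:
    """Pair sister nuclei across every bridge by the geometric score.

    Candidate nuclei for an endpoint lie within ``d_max`` μm of it.  All
    cross-endpoint candidate pairs of every bridge are scored; accepted
    greedily in ascending score order, subject to each bridge pairing once,
    each nucleus being used at most once, and the score ceiling.  Bridges
    without a candidate on either side are skipped and logged.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    centroids = np.array([o.centroid_um for o in nuclei], dtype=float).reshape(-1, 3)
    candidates: list[tuple[float, int, int, int]] = []  # (score, bridge idx, i, j)
    for bi, bridge in enumerate(bridges):
        d1 = np.linalg.norm(centroids - bridge.endpoint_1, axis=1) if len(nuclei) else np.empty(0)
        d2 = np.linalg.norm(centroids - bridge.endpoint_2, axis=1) if len(nuclei) else np.empty(0)
        side1 = np.flatnonzero(d1 <= d_max)
        side2 = np.flatnonzero(d2 <= d_max)
        found = False
        for i in side1:
            for j in side2:
                if i == j:
                    continue
                sep = centroids[j] - centroids[i]
                norm = np.linalg.norm(sep)
                if norm == 0:
                    continue
                cos_theta = abs(float(sep @ bridge.axis)) / norm
                score = (d1[i] + d2[j]) / d_max + lambda_angle * (1.0 - cos_theta)
                if score <= score_ceiling:
                    candidates.append((score, bi, int(i), int(j)))
                    found = True
        if not found:
            logger.info("bridge %d skipped: no admissible sister pair", bridge.bridge_id)

    candidates.sort(key=lambda c: c[0])
    used_nuclei: set[int] = set()
    paired_bridges: set[int] = set()
    axes = []
    for score, bi, i, j in candidates:
        if bi in paired_bridges or i in used_nuclei or j in used_nuclei:
            continue
        paired_bridges.add(bi)
        used_nuclei.update((i, j))
        axes.append(
            axis_from_pair(centroids[i], centroids[j],
                           bridge_id=bridges[bi].bridge_id, score=score)
        )
    return axes


_NEIGHBORS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _farthest_voxel(start, voxel_set):
    """BFS over 26-connected voxels; returns the voxel farthest from start."""
    seen = {start}
    queue = deque([start])
    last = start
    while queue:
        last = queue.popleft()
        z, y, x = last
        for dz, dy, dx in _NEIGHBORS:
            nxt = (z + dz, y + dy, x + dx)
            if nxt in voxel_set and nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return last


def bridges_from_labelmap(label_map: LabelMap) -> list[Bridge]:
    """Extract bridges as the extremal points of each component's skeleton.

    Endpoints are approximated by a double breadth-first sweep (the two ends
    of the longest 26-connected geodesic through the component), converted to
    world (x, y, z) μm.  Single-voxel components cannot define an axis and
    are skipped.
    """
    labels = label_map.labels
    if labels.ndim != 3:
        raise ValueError("bridges_from_labelmap expects a 3D label map")
    dz, dy, dx = label_map.spacing_um
    bridges = []
    for lbl in range(1, label_map.n_objects + 1):
        voxels = list(map(tuple, np.argwhere(labels == lbl)))
        if len(voxels) < 2:
            continue
        voxel_set = set(voxels)
        a = _farthest_voxel(voxels[0], voxel_set)
        b = _farthest_voxel(a, voxel_set)
        p1 = np.array([a[2] * dx, a[1] * dy, a[0] * dz])
        p2 = np.array([b[2] * dx, b[1] * dy, b[0] * dz])
        if np.allclose(p1, p2):
            continue
        bridges.append(Bridge(bridge_id=lbl, endpoint_1=p1, endpoint_2=p2))
    return bridges


def axes_to_axis_set(axes: list[DivisionAxis], specimen=None) -> AxisSet:
    """Collect division axes into an :class:`AxisSet` (positions = midpoints)."""
    if not axes:
        return AxisSet(np.empty((0, 3)), np.empty((0, 3)))
    positions = np.array([a.midpoint for a in axes])
    vectors = np.array([a.axis for a in axes])
    spec = np.asarray(specimen) if specimen is not None else None
    return AxisSet.from_vectors(positions, vectors, spec)
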