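"""Orientation-tensor statistics and regional coordination of division axes.

For sign-symmetric unit axes u₁…uₙ the orientation tensor

    T = (1/n) Σ uᵢ uᵢᵀ

is symmetric positive-semidefinite with unit trace; its largest eigenvalue
E1 measures axial coordination.  For axes confined to a plane E1 ranges from
0.5 (planar isotropy) to 1 (perfect alignment); for free 3D axes the
isotropic value is 1/3.

Significance is assessed against a tangent-plane isotropic null: E1(5%) is
the 95th percentile of E1 over bootstrap replicates of n uniformly oriented
in-plane axes.  For in-plane axes the tensor eigenvalues are
((1 ± R₂)/2, 0) with R₂ the resultant length of the doubled angles, so the
null is simulated directly on angles.  Because a region's null depends only
on its axis count n, thresholds are tabulated per n and, for region scans,
interpolated between pivot sizes linearly in 1/√n (the scale on which
E1 − ½ shrinks under the null).

Regions are geodesic discs grown from template-mesh vertices.  The core
region is the disc with the highest E1 among those holding at least a
minimum number of axes (50 by default); the coordination contour map lists
every disc that contains the core and exceeds its E1(5%), with contour value
E1/E1(5%) (> 1 ⇔ significant at 5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .io_formats import AxisSet, SurfaceMesh, sign_normalize

__all__ = [
    "OrientationStats",
    "BootstrapThreshold",
    "BootstrapThresholdTable",
    "RegionResult",
    "ScanResult",
    "orientation_stats",
    "planar_project",
    "bootstrap_threshold",
    "dual_threshold_retain",
    "scan_regions",
    "mesh_geodesic_distances",
]


@dataclass(frozen=True)
class OrientationStats:
    n: int
    tensor: np.ndarray  # (3, 3)
    eigenvalues: np.ndarray  # sorted descending, sums to 1

    @property
    def e1(self) -> float:
        return float(self.eigenvalues[0])


@dataclass(frozen=True)
class BootstrapThreshold:
    """95th-percentile E1 under the isotropic in-plane null for region size n."""

    n: int
    replicates: int
    value: float


@dataclass(frozen=True)
class RegionResult:
    center_vertex: int
    radius: float
    member_idx: np.ndarray
    n: int
    e1: float
    threshold: float  # E1(5%) for this n
    ratio: float  # contour value E1 / E1(5%)

    @property
    def significant(self) -> bool:
        return self.ratio > 1.0


@dataclass(frozen=True)
class ScanResult:
    core: RegionResult | None
    significant: list[RegionResult]  # regions containing the core with E1 > E1(5%)
    contour: np.ndarray  # per-vertex max contour value (0 where uncovered)
    insufficient: bool = False


# ---------------------------------------------------------------------------
# orientation tensor
# ---------------------------------------------------------------------------


def orientation_stats(axes: AxisSet | np.ndarray) -> OrientationStats:
    """Orientation tensor and sorted eigenvalues of a set of unit axes.

    The tensor uses uuᵀ, so the statistic is sign-symmetric by construction.
    """
    u = axes.axes if isinstance(axes, AxisSet) else np.atleast_2d(np.asarray(axes, float))
    if len(u) < 1:
        raise ValueError("need at least one axis")
    norms = np.linalg.norm(u, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("axes must be unit length")
    tensor = (u.T @ u) / len(u)
    eig = np.linalg.eigvalsh(tensor)[::-1]
    return OrientationStats(n=len(u), tensor=tensor, eigenvalues=eig)


def planar_project(
    axes: AxisSet,
    template: SurfaceMesh,
    eps: float = 0.1,
    max_distance: float | None = None,
) -> tuple[AxisSet, int]:
    """Project axes onto the tangent plane of their nearest template vertex.

    Axes whose planar component norm falls below ``eps`` (axes normal to the
    surface) are excluded; the count of exclusions is returned.  Axes whose
    nearest vertex is farther than ``max_distance`` (if given) are rejected
    with their index.
    """
    verts = template.vertices
    normals = template.vertex_normals
    tree = cKDTree(verts)
    dist, nearest = tree.query(axes.positions)
    if max_distance is not None and np.any(dist > max_distance):
        bad = np.flatnonzero(dist > max_distance)
        raise ValueError(f"no template surface within {max_distance} of axes {bad.tolist()}")
    nrm = normals[nearest]
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    planar = axes.axes - (np.sum(axes.axes * nrm, axis=1, keepdims=True)) * nrm
    norms = np.linalg.norm(planar, axis=1)
    keep = norms >= eps
    excluded = int((~keep).sum())
    kept = AxisSet(
        axes.positions[keep],
        sign_normalize(planar[keep] / norms[keep, None]),
        axes.specimen[keep] if axes.specimen is not None else None,
    )
    return kept, excluded


# ---------------------------------------------------------------------------
# bootstrap null
# ---------------------------------------------------------------------------


def _null_e1_samples(n: int, B: int, rng: np.random.Generator,
                     normals: np.ndarray | None) -> np.ndarray:
    """E1 under the tangent-plane isotropic null: B replicates of n axes."""
    if normals is None:
        # in-plane axial data: eigenvalues ((1 ± R2)/2, 0)
        theta = rng.uniform(0.0, np.pi, size=(B, n))
        c = np.cos(2 * theta).mean(axis=1)
        s = np.sin(2 * theta).mean(axis=1)
        return 0.5 * (1.0 + np.hypot(c, s))
    # position-aware null: uniform directions in the local tangent planes
    normals = np.asarray(normals, float)
    if normals.shape != (n, 3):
        raise ValueError("normals must be (n, 3)")
    nrm = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    ref = np.where(np.abs(nrm[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[0.0, 1.0, 0.0]])
    t1 = np.cross(nrm, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(nrm, t1)
    theta = rng.uniform(0.0, np.pi, size=(B, n))
    u = np.cos(theta)[..., None] * t1 + np.sin(theta)[..., None] * t2  # (B, n, 3)
    T = np.einsum("bni,bnj->bij", u, u) / n
    return np.linalg.eigvalsh(T)[:, -1]


def bootstrap_threshold(
    n: int,
    B: int = 10_000,
    seed: int = 0,
    normals: np.ndarray | None = None,
) -> BootstrapThreshold:
    """E1(5%): the 95th percentile of E1 under the isotropic tangent-plane null.

    By default the null is in-plane axial isotropy, which depends on the
    region size n only.  Passing per-axis surface ``normals`` draws uniform
    directions in each observed tangent plane instead (position-aware null).
    The percentile uses linear interpolation between order statistics.
    """
    if n < 1:
        raise ValueError("region size n must be >= 1")
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if n == 1:
        return BootstrapThreshold(n=1, replicates=B, value=1.0)
    rng = np.random.default_rng(seed)
    e1 = _null_e1_samples(n, B, rng, normals)
    return BootstrapThreshold(n=n, replicates=B,
                              value=float(np.percentile(e1, 95.0)))


def dual_threshold_retain(
    pre: BootstrapThreshold, post: BootstrapThreshold
) -> BootstrapThreshold:
    """Retain the larger of the pre- and post-transport thresholds.

    Computing E1(5%) both before and after diffeomorphic transport and
    keeping the maximum compensates for any spurious tightening of the
    alignment introduced by the transport.
    """
    if pre.n != post.n:
        raise ValueError(f"region size mismatch: {pre.n} vs {post.n}")
    return pre if pre.value >= post.value else post


class BootstrapThresholdTable:
    """E1(5%) lookup for arbitrary region sizes, interpolated between pivots.

    Thresholds are simulated once at pivot sizes and interpolated linearly
    in 1/√n; queries outside the pivot range clamp to the nearest pivot.
    """

    def __init__(self, pivots=(10, 20, 35, 50, 75, 100, 150, 250, 400, 700, 1000),
                 B: int = 10_000, seed: int = 0):
        self.pivots = np.array(sorted(pivots), dtype=int)
        if self.pivots[0] < 2:
            raise ValueError("pivot sizes must be >= 2")
        self.B = B
        self.values = np.array([
            bootstrap_threshold(int(n), B=B, seed=seed + k).value
            for k, n in enumerate(self.pivots)
        ])

    def lookup(self, n: int) -> float:
        if n < 1:
            raise ValueError("region size must be >= 1")
        if n == 1:
            return 1.0
        x = 1.0 / np.sqrt(self.pivots.astype(float))
        xi = 1.0 / np.sqrt(float(n))
        # np.interp needs ascending x; 1/sqrt(pivots) is descending
        return float(np.interp(xi, x[::-1], self.values[::-1]))


# ---------------------------------------------------------------------------
# region scan
# ---------------------------------------------------------------------------


def mesh_geodesic_distances(mesh: SurfaceMesh) -> np.ndarray:
    """All-pairs geodesic distances along mesh edges (Dijkstra on edge graph)."""
    verts = mesh.vertices
    faces = mesh.faces
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)  # COO duplicates would sum
    lengths = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    n = len(verts)
    graph = coo_matrix((np.r_[lengths, lengths],
                        (np.r_[edges[:, 0], edges[:, 1]],
                         np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n))
    return dijkstra(graph.tocsr(), directed=False)


def scan_regions(
    axes: AxisSet,
    mesh: SurfaceMesh,
    radii,
    min_axes: int = 50,
    thresholds: BootstrapThresholdTable | None = None,
    geodesic: np.ndarray | None = None,
) -> ScanResult:
    """Scan geodesic-disc regions for the coordination core and contour map.

    Candidate regions are geodesic discs of every radius in ``radii``
    centered on every mesh vertex; an axis belongs to a disc when its
    nearest mesh vertex lies within the disc.  The core region is the disc
    with the highest E1 among those holding at least ``min_axes`` axes.
    Discs that geodesically contain the core disc and exceed their E1(5%)
    make up the contour map, with contour value E1/E1(5%).  When no disc
    reaches ``min_axes`` an explicit insufficient-axes result is returned.
    """
    if thresholds is None:
        thresholds = BootstrapThresholdTable()
    if geodesic is None:
        geodesic = mesh_geodesic_distances(mesh)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    n_axes = len(axes)
    if n_axes == 0:
        return ScanResult(None, [], np.zeros(len(mesh.vertices)), insufficient=True)

    tree = cKDTree(mesh.vertices)
    _, nearest = tree.query(axes.positions)

    # per-axis outer products, flattened for fast per-region sums
    outer = np.einsum("ni,nj->nij", axes.axes, axes.axes).reshape(n_axes, 9)

    regions: list[tuple[int, float, np.ndarray]] = []
    e1s: list[float] = []
    counts: list[int] = []
    n_vertices = len(mesh.vertices)
    for radius in radii:
        member = geodesic[:, nearest] <= radius  # (V, n_axes)
        cnt = member.sum(axis=1)
        sums = member @ outer  # (V, 9)
        for v in range(n_vertices):
            if cnt[v] < 1:
                continue
            regions.append((v, float(radius), np.flatnonzero(member[v])))
            T = sums[v].reshape(3, 3) / cnt[v]
            e1s.append(float(np.linalg.eigvalsh(T)[-1]))
            counts.append(int(cnt[v]))

    eligible = [k for k in range(len(regions)) if counts[k] >= min_axes]
    if not eligible:
        return ScanResult(None, [], np.zeros(n_vertices), insufficient=True)

    core_k = max(eligible, key=lambda k: e1s[k])
    cv, cr, cmembers = regions[core_k]
    core_thr = thresholds.lookup(counts[core_k])
    core = RegionResult(cv, cr, cmembers, counts[core_k], e1s[core_k],
                        core_thr, e1s[core_k] / core_thr)

    significant = []
    contour = np.zeros(n_vertices)
    for k, (v, radius, members) in enumerate(regions):
        # geodesic containment of the core disc
        if geodesic[v, cv] + cr > radius + 1e-9:
            continue
        thr = thresholds.lookup(counts[k])
        if e1s[k] > thr:
            region = RegionResult(v, radius, members, counts[k], e1s[k],
                                  thr, e1s[k] / thr)
            significant.append(region)
            covered = geodesic[v] <= radius
            contour[covered] = np.maximum(contour[covered], region.ratio)
    return ScanResult(core, significant, contour)
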