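"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the library
(fixed-point label propagation instead of union-find labelling, FFT
differentiation instead of finite differences, matrix square roots instead
of SVD polar factors, exhaustive search instead of greedy selection) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def label_components_oracle(foreground: np.ndarray) -> np.ndarray:
    """Connected components by fixed-point minimum-label propagation.

    Full-neighborhood connectivity (8 in 2D, 26 in 3D).  Every foreground
    voxel starts with a unique label; labels propagate to the minimum over
    the neighborhood until nothing changes.
    """
    fg = np.asarray(foreground).astype(bool)
    lab = np.where(fg, np.arange(1, fg.size + 1, dtype=float).reshape(fg.shape), np.inf)
    offsets = [
        off for off in itertools.product((-1, 0, 1), repeat=fg.ndim)
        if any(off)
    ]
    while True:
        new = lab.copy()
        for off in offsets:
            src = tuple(
                slice(max(-o, 0), fg.shape[d] - max(o, 0)) for d, o in enumerate(off)
            )
            dst = tuple(
                slice(max(o, 0), fg.shape[d] - max(-o, 0)) for d, o in enumerate(off)
            )
            new[dst] = np.minimum(new[dst], lab[src])
        new[~fg] = np.inf
        if np.array_equal(new, lab, equal_nan=False):
            break
        lab = new
    # relabel consecutively in first-seen order
    out = np.zeros(fg.shape, dtype=np.int32)
    seen: dict[float, int] = {}
    flat_lab = lab.ravel()
    flat_out = out.ravel()
    for i in np.flatnonzero(fg.ravel()):
        root = flat_lab[i]
        if root not in seen:
            seen[root] = len(seen) + 1
        flat_out[i] = seen[root]
    return out


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label images induce the same foreground partition."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or np.any((a > 0) != (b > 0)):
        return False
    pairs = np.unique(np.stack([a[a > 0], b[a > 0]]), axis=1)
    return (
        len(np.unique(pairs[0])) == pairs.shape[1]
        and len(np.unique(pairs[1])) == pairs.shape[1]
    )


def spectral_jacobian(disp: np.ndarray, spacing) -> np.ndarray:
    """Exact Jacobian of a periodic displacement grid by FFT differentiation."""
    disp = np.asarray(disp, dtype=float)
    shape = disp.shape[:3]
    J = np.empty((*shape, 3, 3))
    for c in range(3):
        F = np.fft.fftn(disp[..., c])
        for d in range(3):
            k = 2j * np.pi * np.fft.fftfreq(shape[d], d=spacing[d])
            shape_k = [1, 1, 1]
            shape_k[d] = shape[d]
            J[..., c, d] = np.real(np.fft.ifftn(F * k.reshape(shape_k)))
    J += np.eye(3)
    return J


def polar_rotation_sqrtm(J: np.ndarray) -> np.ndarray:
    """Polar rotation via R = J (JᵀJ)^(−1/2) using an eigendecomposition root."""
    J = np.asarray(J, dtype=float)
    S2 = J.T @ J
    w, V = np.linalg.eigh(S2)
    S_inv = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    return J @ S_inv


def polar_rotation_search(J: np.ndarray, n_starts: int = 20, seed: int = 0) -> np.ndarray:
    """Polar rotation by direct minimization of ||J − R||_F over rotations.

    Samples random unit quaternions and refines the best with Nelder–Mead.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    J = np.asarray(J, dtype=float)

    def cost(q):
        q = q / np.linalg.norm(q)
        return np.linalg.norm(J - Rotation.from_quat(q).as_matrix())

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0 / np.linalg.norm(q0), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    q = best.x / np.linalg.norm(best.x)
    return Rotation.from_quat(q).as_matrix()


def best_pairs_exhaustive(bridges, nuclei, lambda_angle, d_max, ceiling):
    """Per-bridge exhaustive minimum-score sister pair (no nucleus sharing check).

    Valid as a global optimum when bridges' candidate sets are disjoint.
    Returns {bridge_id: (i, j, score)} for bridges with an admissible pair.
    """
    centroids = np.array([o.centroid_um for o in nuclei], dtype=float)
    out = {}
    for bridge in bridges:
        d1 = np.linalg.norm(centroids - bridge.endpoint_1, axis=1)
        d2 = np.linalg.norm(centroids - bridge.endpoint_2, axis=1)
        best = None
        for i in np.flatnonzero(d1 <= d_max):
            for j in np.flatnonzero(d2 <= d_max):
                if i == j:
                    continue
                sep = centroids[j] - centroids[i]
                norm = np.linalg.norm(sep)
                if norm == 0:
                    continue
                cos_t = abs(float(sep @ bridge.axis)) / norm
                score = (d1[i] + d2[j]) / d_max + lambda_angle * (1 - cos_t)
                if score <= ceiling and (best is None or score < best[2]):
                    best = (int(i), int(j), score)
        if best is not None:
            out[bridge.bridge_id] = best
    return out


def fan_triangulation_area(vertices: np.ndarray) -> float:
    """Polygon area by fan triangulation from the first vertex (convex input)."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for k in range(1, len(v) - 1):
        a = v[k] - v[0]
        b = v[k + 1] - v[0]
        total += 0.5 * abs(a[0] * b[1] - a[1] * b[0])
    return total
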