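"""Surface templates and diffeomorphic transport of division axes.

Pooling axial data from several specimens requires (i) an average organ
envelope (the template) and (ii) a smooth invertible deformation carrying
each specimen onto it.  Axis *positions* are mapped through the deformation
φ; axis *directions* are rotated by the polar (rotational) part of the
Jacobian of φ at the axis midpoint.  Using only the rotational part is what
guarantees that a deformation cannot spuriously tighten or loosen the axial
distribution: a pure stretch leaves every direction — and hence the
orientation-tensor eigenvalue E1 — exactly unchanged.

Templates are estimated by generalized Procrustes analysis (rigid alignment,
no scaling) followed by a vertex-wise mean over corresponded envelopes.
Deformations are represented as displacement grids; diffeomorphisms are
generated from stationary velocity fields by scaling and squaring,
φ = exp(v).  Variational (LDDMM-style) template matching is out of scope:
every downstream statistic depends only on having some valid φ and its
Jacobian.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from scipy.linalg import polar as _scipy_polar

from .io_formats import AxisSet, SurfaceMesh, sign_normalize

__all__ = [
    "DeformationField",
    "TemplateMesh",
    "InvertibilityError",
    "integrate_velocity",
    "jacobian_at",
    "polar_rotation",
    "transport_axes",
    "build_template",
    "save_field",
    "load_field",
]


class InvertibilityError(ValueError):
    """Raised when a deformation's Jacobian determinant is not positive."""


@dataclass
class DeformationField:
    """Displacement field u on a regular grid; the map is φ(x) = x + u(x).

    The grid is indexed ``(i, j, k)`` along world axes ``(x, y, z)``;
    ``disp[..., c]`` is the c-th displacement component in μm.  Off-grid
    values are obtained by trilinear interpolation (``mode`` follows
    :func:`scipy.ndimage.map_coordinates`: 'nearest' clamps, 'grid-wrap' is
    periodic).
    """

    origin: np.ndarray  # (3,) xyz μm
    spacing: np.ndarray  # (3,) μm
    disp: np.ndarray  # (nx, ny, nz, 3) μm
    mode: str = "nearest"
    _jac_grid: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[3] != 3:
            raise ValueError("disp must be (nx, ny, nz, 3)")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, shape, spacing, origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        return cls(np.asarray(origin, float), np.asarray(spacing, float),
                   np.zeros((*shape, 3)))

    @classmethod
    def from_affine(cls, A, b, shape, spacing, origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        """Sample φ(x) = A x + b on the grid (u = (A − I) x + b)."""
        A = np.asarray(A, float)
        b = np.asarray(b, float)
        pts = cls.identity(shape, spacing, origin).grid_points()
        disp = pts @ (A - np.eye(3)).T + b
        return cls(np.asarray(origin, float), np.asarray(spacing, float), disp)

    # -- geometry ----------------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of all grid nodes, shape (nx, ny, nz, 3)."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.grid_shape[d])
                for d in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def _to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) / self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self._to_index(points)
        hi = np.array(self.grid_shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=-1)

    def _interp(self, grid: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of a scalar grid at physical points."""
        idx = self._to_index(points)
        return ndimage.map_coordinates(grid, idx.reshape(-1, 3).T, order=1,
                                       mode=self.mode).reshape(idx.shape[:-1])

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.stack([self._interp(self.disp[..., c], pts) for c in range(3)], axis=-1)
        return out if np.asarray(points).ndim > 1 else out[0]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) + self.displacement_at(points)

    # -- differential structure -------------------------------------------

    def jacobian_grid(self) -> np.ndarray:
        """J = ∂φ/∂x at every grid node, shape (nx, ny, nz, 3, 3).

        Central finite differences at native grid spacing in the interior;
        one-sided differences on the boundary (``numpy.gradient`` contract).
        """
        if self._jac_grid is None:
            J = np.empty((*self.grid_shape, 3, 3))
            for c in range(3):
                grads = np.gradient(self.disp[..., c], *self.spacing, edge_order=1)
                for d in range(3):
                    J[..., c, d] = grads[d]
            J += np.eye(3)
            self._jac_grid = J
        return self._jac_grid

    def check_invertible(self) -> float:
        """Verify det(J) > 0 at every node; return the minimum determinant."""
        det = np.linalg.det(self.jacobian_grid())
        if det.min() <= 0:
            loc = np.unravel_index(int(det.argmin()), det.shape)
            point = self.origin + self.spacing * np.array(loc)
            raise InvertibilityError(
                f"det(J) = {det.min():.4g} <= 0 at grid node {loc} (x={point})"
            )
        return float(det.min())


def jacobian_at(phi: DeformationField, points: np.ndarray, warn_boundary: bool = True) -> np.ndarray:
    """Jacobian matrix of φ at physical points, shape (..., 3, 3).

    The finite-difference Jacobian grid is interpolated trilinearly.  Points
    within one grid cell of the boundary rely on one-sided differences and
    are flagged with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if not np.all(phi.contains(pts)):
        bad = np.flatnonzero(~phi.contains(pts))
        raise ValueError(f"points outside deformation domain at indices {bad.tolist()}")
    if warn_boundary:
        idx = phi._to_index(pts)
        hi = np.array(phi.grid_shape) - 2
        on_edge = np.any((idx < 1) | (idx > hi), axis=-1)
        if np.any(on_edge):
            warnings.warn(
                f"{int(on_edge.sum())} point(s) near the grid boundary use "
                "one-sided differences",
                stacklevel=2,
            )
    Jg = phi.jacobian_grid()
    out = np.empty((len(pts), 3, 3))
    for c in range(3):
        for d in range(3):
            out[:, c, d] = phi._interp(Jg[..., c, d], pts)
    return out if np.asarray(points).ndim > 1 else out[0]


def integrate_velocity(
    v: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    steps: int = 8,
    mode: str = "nearest",
) -> DeformationField:
    """Exponentiate a stationary velocity grid: φ = exp(v) by scaling and squaring.

    The velocity is scaled by 2^-steps, then the displacement is recursively
    self-composed ``steps`` times: u ← u + u∘(id + u).  Invertibility is
    certified by checking det(J) > 0 at every node.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 4 or v.shape[3] != 3:
        raise ValueError("velocity must be (nx, ny, nz, 3)")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    phi = DeformationField(np.asarray(origin, float), np.asarray(spacing, float),
                           v / (2.0**steps), mode=mode)
    pts = phi.grid_points()
    for _ in range(steps):
        disp = phi.disp + phi.displacement_at(pts + phi.disp)
        phi = DeformationField(phi.origin, phi.spacing, disp, mode=mode)
    phi.check_invertible()
    return phi


def polar_rotation(J: np.ndarray) -> np.ndarray:
    """Rotation part R of the polar decomposition J = R·S (S symmetric PD).

    Accepts a single 3×3 matrix or a batch (..., 3, 3); requires det(J) > 0,
    which makes det(R) = +1 automatic.
    """
    J = np.asarray(J, dtype=float)
    single = J.ndim == 2
    Jb = J[None] if single else J.reshape(-1, 3, 3)
    det = np.linalg.det(Jb)
    if np.any(det <= 0):
        raise ValueError("polar_rotation requires det(J) > 0 (singular or reflecting J)")
    if single:
        R = _scipy_polar(J)[0]
        return R
    U, _, Vt = np.linalg.svd(Jb)
    R = U @ Vt
    return R.reshape(J.shape)


def transport_axes(axes: AxisSet, phi: DeformationField) -> AxisSet:
    """Transport an axis set through φ.

    Positions map by φ; directions rotate by the polar part of the Jacobian
    at the axis midpoint, then are renormalized and sign-normalized.  The
    stretch part of J is discarded deliberately, so the transport cannot
    alter axial coordination statistics by deformation alone.
    """
    inside = phi.contains(axes.positions)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        raise ValueError(f"axis position(s) outside domain at indices {bad.tolist()}")
    new_pos = phi(axes.positions)
    J = jacobian_at(phi, axes.positions, warn_boundary=False)
    R = polar_rotation(J)
    rotated = np.einsum("nij,nj->ni", R, axes.axes)
    rotated /= np.linalg.norm(rotated, axis=1, keepdims=True)
    return AxisSet(new_pos, sign_normalize(rotated), axes.specimen)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateMesh:
    """Average envelope plus the rigid transform aligning each specimen to it."""

    mesh: SurfaceMesh
    rotations: np.ndarray  # (S, 3, 3)
    translations: np.ndarray  # (S, 3)


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid (R, t) minimizing ||R·moving + t − target||, no scaling."""
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    H = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def build_template(
    envelopes: list[SurfaceMesh],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> TemplateMesh:
    """Average corresponded envelopes by generalized Procrustes analysis.

    All envelopes must share vertex correspondence (equal vertex counts,
    matching topology).  Each iteration rigidly aligns every envelope to the
    current mean and recomputes the vertex-wise mean, until the mean moves
    less than ``tol`` (RMS, μm).
    """
    if not envelopes:
        raise ValueError("need at least one envelope")
    counts = {len(m.vertices) for m in envelopes}
    if len(counts) != 1:
        raise ValueError(f"mismatched vertex counts: {sorted(counts)}")
    faces = envelopes[0].faces
    verts = [m.vertices for m in envelopes]
    template = verts[0] - verts[0].mean(axis=0)
    rotations = [np.eye(3)] * len(verts)
    translations = [np.zeros(3)] * len(verts)
    for _ in range(max_iter):
        aligned = []
        rotations, translations = [], []
        for v in verts:
            R, t = _kabsch(v, template)
            rotations.append(R)
            translations.append(t)
            aligned.append(v @ R.T + t)
        new_template = np.mean(aligned, axis=0)
        shift = np.sqrt(np.mean(np.sum((new_template - template) ** 2, axis=1)))
        template = new_template
        if shift < tol:
            break
    return TemplateMesh(SurfaceMesh(template, faces),
                        np.array(rotations), np.array(translations))


# ---------------------------------------------------------------------------
# on-disk representation: 3-component displacement TIFF + JSON header
# ---------------------------------------------------------------------------


def save_field(phi: DeformationField, tiff_path, header_path) -> None:
    """Store the displacement grid as a 3-page-per-slice float TIFF + JSON header."""
    pages = np.moveaxis(phi.disp, -1, 0).astype(np.float32)  # (3, nx, ny, nz)
    tifffile.imwrite(str(tiff_path), pages.reshape(-1, *pages.shape[2:]),
                     photometric="minisblack")
    header = {
        "origin_um": phi.origin.tolist(),
        "spacing_um": phi.spacing.tolist(),
        "grid_shape": list(phi.grid_shape),
        "mode": phi.mode,
    }
    with open(header_path, "w") as fh:
        json.dump(header, fh, indent=1)


def load_field(tiff_path, header_path) -> DeformationField:
    with open(header_path) as fh:
        header = json.load(fh)
    shape = tuple(header["grid_shape"])
    pages = tifffile.imread(str(tiff_path))
    disp = np.moveaxis(pages.reshape(3, *shape), 0, -1).astype(float)
    return DeformationField(
        np.array(header["origin_um"]), np.array(header["spacing_um"]), disp,
        mode=header.get("mode", "nearest"),
    )
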