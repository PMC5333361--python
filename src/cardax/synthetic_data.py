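"""Ground-truthed synthetic scenes for every pipeline stage.

No imaging data ships with the package; instead this module generates 3D
multi-channel scenes with the statistical structure the analysis assumes,
together with truth tables sufficient to score every downstream stage
(detection recall, nuclear-fraction recovery, axis-bias recovery, reporter
classification) without re-inspecting the images.

Scene model
-----------
Nuclei are rendered as anisotropy-aware Gaussian blobs whose half-maximum
isosurface is a sphere of the planted radius; the cell body is a concentric
sphere ``cell_radius_factor`` times larger, so the cytoplasm is a shell.
Protein signal is split between nucleus and cytoplasm by the planted nuclear
fraction ``f_nuc``.  Mitotic (PH3+) nuclei are an independent Bernoulli draw;
cytokinetic bridges join planted sister-nucleus pairs.  Two-channel reporter
signal around each nucleus comes from a two-component bivariate Gaussian
mixture.  Photon (Poisson) noise is applied before Gaussian read noise,
the conventional camera model.

Axis fields are sampled on a surface mesh: each axis lies in the local
tangent plane, with its in-plane angle drawn from a (sign-symmetrized)
von Mises distribution around the projected bias direction; concentration
κ = 0 gives tangent-plane isotropy, κ → ∞ the bias direction itself.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AxisSet, MultiChannelStack, SurfaceMesh
from .shape_registration import DeformationField, InvertibilityError, integrate_velocity

__all__ = [
    "SceneSpec",
    "ReporterSpec",
    "SceneTruth",
    "AxisFieldSpec",
    "AxisFieldTruth",
    "SceneOvercrowdedError",
    "make_scene",
    "make_axis_field",
    "make_deformation",
]

ALL_CHANNELS = ("nuclei", "myocyte", "ph3", "bridge", "protein", "gfp", "tomato")


class SceneOvercrowdedError(RuntimeError):
    """Requested nuclei cannot be placed without violating min separation."""


@dataclass(frozen=True)
class ReporterSpec:
    """Two bivariate reporter clusters (e.g. GFP-high vs Tomato-high)."""

    mean_a: tuple[float, float] = (200.0, 20.0)
    mean_b: tuple[float, float] = (20.0, 200.0)
    sd: float = 5.0
    frac_a: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_a <= 1.0:
            raise ValueError("frac_a must lie in [0, 1]")
        if self.sd <= 0:
            raise ValueError("reporter sd must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic tissue scene; identical seed ⇒ identical scene."""

    shape: tuple[int, int, int] = (16, 128, 128)  # (z, y, x) voxels
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nuclei: int = 50
    nucleus_radius_um: tuple[float, float] = (2.5, 0.25)  # (mean, sd)
    frac_mitotic: float = 0.0
    n_bridges: int = 0
    f_nuc: float = 0.5
    background: float = 10.0
    signal: float = 100.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    reporters: ReporterSpec | None = None
    channels: tuple[str, ...] = ("nuclei",)
    min_separation_factor: float = 1.5
    separation_basis: str = "nucleus"  # or "cell"
    cell_radius_factor: float = 2.0
    sister_distance_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_mitotic <= 1.0 or not 0.0 <= self.f_nuc <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.nucleus_radius_um[0] <= 0 or self.signal <= 0 or self.background < 0:
            raise ValueError("radii and intensities must be positive")
        if self.n_nuclei < 0 or self.n_bridges < 0:
            raise ValueError("counts must be >= 0")
        if 2 * self.n_bridges > self.n_nuclei:
            raise ValueError("need two nuclei per bridge")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")
        if self.separation_basis not in ("nucleus", "cell"):
            raise ValueError("separation_basis must be 'nucleus' or 'cell'")


@dataclass
class SceneTruth:
    """Ground truth for a generated scene.

    ``nuclei`` columns: nucleus_id, x_um, y_um, z_um, radius_um, volume_um3,
    mitotic, f_nuc, reporter_class ('A'|'B'|''), bridge_id (-1 if unpaired).
    Label grids are indexed (z, y, x); label i+1 marks nucleus/cell id i.
    """

    nuclei: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    sister_pairs: pd.DataFrame  # bridge_id, nucleus_a, nucleus_b, endpoints (xyz μm)


@dataclass(frozen=True)
class AxisFieldSpec:
    """Tangent-plane axis field on a surface mesh."""

    mesh: SurfaceMesh
    n: int = 100
    kappa: float = 0.0
    bias: tuple[float, float, float] = (1.0, 0.0, 0.0)
    patch_frac: float | None = None  # fraction of axes in the coordinated patch
    patch_center: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("concentration kappa must be >= 0")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.patch_frac is not None and not 0.0 < self.patch_frac <= 1.0:
            raise ValueError("patch_frac must lie in (0, 1]")


@dataclass(frozen=True)
class AxisFieldTruth:
    in_patch: np.ndarray  # (n,) bool — axes drawn with concentration kappa
    patch_center: np.ndarray | None
    patch_radius: float | None  # Euclidean radius defining the patch


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator):
    """Sample centres (xyz μm) and radii subject to the separation rule."""
    dz, dy, dx = spec.spacing_um
    extent = np.array([spec.shape[2] * dx, spec.shape[1] * dy, spec.shape[0] * dz])
    radii = np.abs(rng.normal(*spec.nucleus_radius_um, size=spec.n_nuclei))
    radii = np.maximum(radii, 0.2 * spec.nucleus_radius_um[0])
    sep_radii = radii * (spec.cell_radius_factor if spec.separation_basis == "cell" else 1.0)
    margin_scale = spec.cell_radius_factor
    if np.any(2.0 * radii.max(initial=0.0) >= extent.min()):
        raise SceneOvercrowdedError("grid too small for the requested nucleus radius")

    def margin_for(r: float) -> np.ndarray:
        # keep the whole cell inside where the grid allows; at minimum keep
        # the nucleus inside (cells may clip at thin-stack boundaries)
        want = margin_scale * r + 1.0
        return np.clip(want, r, extent / 2.0 - 1e-3)

    centers = np.empty((spec.n_nuclei, 3))
    n_placed = 0
    max_attempts = 300 * max(spec.n_nuclei, 1)
    attempts = 0

    pair_of = np.full(spec.n_nuclei, -1, dtype=int)

    def try_place(r_sep, margin, paired_with=None, sibling=None):
        # sisters are exempt from the full separation rule (they sit side by
        # side at cytokinesis); they only must not overlap
        nonlocal attempts
        while attempts < max_attempts:
            attempts += 1
            if paired_with is None:
                c = rng.uniform(margin, extent - margin)
            else:
                mid, direction = paired_with
                c = mid + direction
            if np.any(c < margin) or np.any(c > extent - margin):
                if paired_with is not None:
                    return None
                continue
            if n_placed:
                d = np.linalg.norm(centers[:n_placed] - c, axis=1)
                min_d = spec.min_separation_factor * (sep_radii[:n_placed] + r_sep)
                if sibling is not None:
                    min_d[sibling] = radii[:n_placed][sibling] + r_sep
                if np.any(d < min_d):
                    if paired_with is not None:
                        return None
                    continue
            return c
        raise SceneOvercrowdedError(
            f"placed {n_placed}/{spec.n_nuclei} nuclei in {attempts} attempts; "
            "reduce n_nuclei or min_separation_factor"
        )

    # sister pairs first: two nuclei at sister_distance_um around a midpoint
    for b in range(spec.n_bridges):
        while True:
            i, j = n_placed, n_placed + 1
            margin = margin_for(max(radii[i], radii[j]))
            if np.any(margin >= extent - margin):
                raise SceneOvercrowdedError("grid too small for sister pairs")
            # out-of-bounds endpoints are rejected by try_place and retried
            mid = rng.uniform(margin, extent - margin)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            offset = 0.5 * spec.sister_distance_um * u
            c1 = try_place(sep_radii[i], margin, paired_with=(mid, offset))
            if c1 is None:
                continue
            centers[i] = c1
            n_placed += 1
            c2 = try_place(sep_radii[j], margin, paired_with=(mid, -offset),
                           sibling=i)
            if c2 is None:
                n_placed -= 1  # retry the whole pair
                continue
            centers[j] = c2
            n_placed += 1
            pair_of[i], pair_of[j] = b, b
            break
    for i in range(2 * spec.n_bridges, spec.n_nuclei):
        centers[i] = try_place(sep_radii[i], margin_for(radii[i]))
        n_placed += 1
    return centers, radii, pair_of


def _stamp(grid: np.ndarray, spacing_zyx, center_xyz, radius_um, fn) -> None:
    """Apply ``grid[patch] = fn(r_um, existing)`` on a local patch around a centre.

    ``fn`` receives the physical distance-to-centre array of the patch and the
    existing patch values, and returns the new patch values.
    """
    dz, dy, dx = spacing_zyx
    cx, cy, cz = center_xyz
    c_idx = np.array([cz / dz, cy / dy, cx / dx])
    half = np.array([radius_um / dz, radius_um / dy, radius_um / dx])
    lo = np.maximum(np.floor(c_idx - half).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + half).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * dz - cz)[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * dy - cy)[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * dx - cx)[None, None, :]
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    grid[sl] = fn(r, grid[sl])


def _stamp_blob(grid, spacing, center, radius_um, amplitude) -> None:
    """Gaussian blob whose half-maximum isosurface has the given radius."""
    sigma = radius_um / np.sqrt(2.0 * np.log(2.0))
    _stamp(grid, spacing, center, 3.0 * radius_um,
           lambda r, old: old + amplitude * np.exp(-(r**2) / (2.0 * sigma**2)))


def _stamp_cylinder(grid, spacing, p1_xyz, p2_xyz, radius_um, value) -> None:
    """Constant-intensity capsule between two points (for bridges)."""
    p1 = np.asarray(p1_xyz, float)
    p2 = np.asarray(p2_xyz, float)
    center = 0.5 * (p1 + p2)
    half_len = 0.5 * np.linalg.norm(p2 - p1)
    axis = (p2 - p1) / max(np.linalg.norm(p2 - p1), 1e-12)
    dz, dy, dx = spacing
    reach = half_len + radius_um
    cx, cy, cz = center
    c_idx = np.array([cz / dz, cy / dy, cx / dx])
    half = np.array([reach / dz, reach / dy, reach / dx])
    lo = np.maximum(np.floor(c_idx - half).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + half).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(np.arange(lo[0], hi[0]) * dz,
                             np.arange(lo[1], hi[1]) * dy,
                             np.arange(lo[2], hi[2]) * dx, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1) - p1
    t = np.clip(pts @ axis, 0.0, 2.0 * half_len)
    closest = t[..., None] * axis
    dist = np.linalg.norm(pts - closest, axis=-1)
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    grid[sl][dist <= radius_um] = value


def make_scene(spec: SceneSpec) -> tuple[MultiChannelStack, SceneTruth]:
    """Generate a multi-channel scene and its ground truth.

    Returns a stack holding the channels requested in ``spec.channels`` (in
    :data:`ALL_CHANNELS` order) and a :class:`SceneTruth` with per-object
    centroids, volumes, mitotic flags, planted nuclear fractions, reporter
    classes and sister-pair geometry.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    spacing = spec.spacing_um
    voxel_volume = spacing[0] * spacing[1] * spacing[2]
    channels = tuple(c for c in ALL_CHANNELS if c in spec.channels)

    grids = {c: np.zeros(spec.shape, dtype=np.float64) for c in channels}
    nucleus_labels = np.zeros(spec.shape, dtype=np.int32)
    cell_labels = np.zeros(spec.shape, dtype=np.int32)

    if spec.n_nuclei == 0:
        stack_arr = np.stack(
            [np.full(spec.shape, spec.background) for _ in channels], axis=-1
        ) if channels else np.zeros((*spec.shape, 0))
        truth = SceneTruth(
            nuclei=pd.DataFrame(
                columns=["nucleus_id", "x_um", "y_um", "z_um", "radius_um",
                         "volume_um3", "mitotic", "f_nuc", "reporter_class",
                         "bridge_id"]
            ),
            nucleus_labels=nucleus_labels,
            cell_labels=cell_labels,
            sister_pairs=pd.DataFrame(
                columns=["bridge_id", "nucleus_a", "nucleus_b",
                         "e1x", "e1y", "e1z", "e2x", "e2y", "e2z"]
            ),
        )
        return _finalize_stack(stack_arr, channels, spec, rng), truth

    centers, radii, pair_of = _place_nuclei(spec, rng)
    mitotic = rng.random(spec.n_nuclei) < spec.frac_mitotic
    reporter_class = np.full(spec.n_nuclei, "", dtype=object)
    if spec.reporters is not None:
        reporter_class[:] = np.where(
            rng.random(spec.n_nuclei) < spec.reporters.frac_a, "A", "B"
        )

    cell_radii = spec.cell_radius_factor * radii

    # label grids (exact ellipsoidal masks at the planted radii)
    for i in range(spec.n_nuclei):
        _stamp(cell_labels, spacing, centers[i], cell_radii[i],
               lambda r, old, i=i: np.where((r <= cell_radii[i]) & (old == 0), i + 1, old))
    for i in range(spec.n_nuclei):
        _stamp(nucleus_labels, spacing, centers[i], radii[i],
               lambda r, old, i=i: np.where(r <= radii[i], i + 1, old))

    for i in range(spec.n_nuclei):
        c, r = centers[i], radii[i]
        if "nuclei" in grids:
            _stamp_blob(grids["nuclei"], spacing, c, r, spec.signal)
        if "ph3" in grids and mitotic[i]:
            _stamp_blob(grids["ph3"], spacing, c, r, spec.signal)
        if "myocyte" in grids:
            _stamp(grids["myocyte"], spacing, c, cell_radii[i],
                   lambda rr, old, rc=cell_radii[i]: np.where(rr <= rc, spec.signal, old))
        if "protein" in grids:
            # total amount T = signal × V_cell split by f_nuc between compartments
            v_cell = 4.0 / 3.0 * np.pi * cell_radii[i] ** 3
            v_nuc = 4.0 / 3.0 * np.pi * r**3
            v_cyt = v_cell - v_nuc
            c_nuc = spec.f_nuc * spec.signal * v_cell / v_nuc
            c_cyt = (1.0 - spec.f_nuc) * spec.signal * v_cell / v_cyt
            _stamp(grids["protein"], spacing, c, cell_radii[i],
                   lambda rr, old, r=r, rc=cell_radii[i]: np.where(
                       rr <= r, c_nuc, np.where(rr <= rc, c_cyt, old)))
        if spec.reporters is not None and ("gfp" in grids or "tomato" in grids):
            mean = spec.reporters.mean_a if reporter_class[i] == "A" else spec.reporters.mean_b
            vals = rng.normal(mean, spec.reporters.sd)
            box = 2.0 * r
            for chan, val in zip(("gfp", "tomato"), vals):
                if chan in grids:
                    _stamp(grids[chan], spacing, c, box,
                           lambda rr, old, r=r, box=box, val=max(val, 0.0): np.where(
                               (rr <= box) & (rr > r), val, old))

    # bridges between planted sister pairs
    pairs = []
    for b in range(spec.n_bridges):
        i, j = 2 * b, 2 * b + 1
        c1, c2 = centers[i], centers[j]
        u = (c2 - c1) / np.linalg.norm(c2 - c1)
        # bridge spans the middle half of the sister segment
        e1 = 0.5 * (c1 + c2) - 0.25 * np.linalg.norm(c2 - c1) * u
        e2 = 0.5 * (c1 + c2) + 0.25 * np.linalg.norm(c2 - c1) * u
        if "bridge" in grids:
            _stamp_cylinder(grids["bridge"], spacing, e1, e2, 0.8, spec.signal)
        pairs.append((b, i, j, *e1, *e2))

    stack_arr = np.stack([spec.background + grids[c] for c in channels], axis=-1)
    stack = _finalize_stack(stack_arr, channels, spec, rng)

    nuclei = pd.DataFrame(
        {
            "nucleus_id": np.arange(spec.n_nuclei),
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
            "z_um": centers[:, 2],
            "radius_um": radii,
            "volume_um3": 4.0 / 3.0 * np.pi * radii**3,
            "mitotic": mitotic,
            "f_nuc": spec.f_nuc,
            "reporter_class": reporter_class,
            "bridge_id": pair_of,
        }
    )
    sister_pairs = pd.DataFrame(
        pairs,
        columns=["bridge_id", "nucleus_a", "nucleus_b",
                 "e1x", "e1y", "e1z", "e2x", "e2y", "e2z"],
    )
    return stack, SceneTruth(nuclei, nucleus_labels, cell_labels, sister_pairs)


def _finalize_stack(arr: np.ndarray, channels, spec: SceneSpec,
                    rng: np.random.Generator) -> MultiChannelStack:
    if spec.poisson_noise:
        arr = rng.poisson(np.maximum(arr, 0.0)).astype(np.float64)
    if spec.gaussian_noise_sd > 0:
        arr = arr + rng.normal(0.0, spec.gaussian_noise_sd, size=arr.shape)
    arr = np.maximum(arr, 0.0).astype(np.float32)
    return MultiChannelStack(arr, tuple(channels), spec.spacing_um)


# ---------------------------------------------------------------------------
# axis fields
# ---------------------------------------------------------------------------


def _sample_surface(mesh: SurfaceMesh, n: int, rng: np.random.Generator):
    """Area-weighted surface sampling; returns points and face normals."""
    tm = mesh.to_trimesh()
    areas = tm.area_faces
    faces = rng.choice(len(areas), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    tri = tm.triangles[faces]
    pts = ((1 - r1)[:, None] * tri[:, 0]
           + (r1 * (1 - r2))[:, None] * tri[:, 1]
           + (r1 * r2)[:, None] * tri[:, 2])
    normals = np.asarray(tm.face_normals)[faces]
    return pts, normals


def make_axis_field(spec: AxisFieldSpec) -> tuple[AxisSet, AxisFieldTruth]:
    """Sample a tangent-plane axis field on a mesh.

    Each sampled point gets a tangent frame whose first vector is the bias
    direction projected onto the tangent plane; the in-plane angle is drawn
    from a von Mises distribution with concentration κ (κ = 0 uniform,
    κ ≥ 1e6 exactly the bias).  If ``patch_frac`` is set, only the axes inside
    a surface patch around ``patch_center`` are concentrated; the rest are
    tangent-plane isotropic.  The patch is the ``patch_frac`` quantile ball of
    Euclidean distance to the patch centre, so the planted coordinated
    fraction is exact.
    """
    rng = np.random.default_rng(spec.seed)
    pts, normals = _sample_surface(spec.mesh, spec.n, rng)

    bias = np.asarray(spec.bias, float)
    t1 = bias[None, :] - (normals @ bias)[:, None] * normals
    t1_norm = np.linalg.norm(t1, axis=1)
    degenerate = t1_norm < 1e-8
    if np.any(degenerate):
        # arbitrary tangent where the bias is normal to the surface
        alt = np.cross(normals[degenerate], [0.0, 0.0, 1.0])
        alt_norm = np.linalg.norm(alt, axis=1)
        flat = alt_norm < 1e-8
        alt[flat] = np.cross(normals[degenerate][flat], [0.0, 1.0, 0.0])
        t1[degenerate] = alt
        t1_norm = np.linalg.norm(t1, axis=1)
    t1 /= t1_norm[:, None]
    t2 = np.cross(normals, t1)

    if spec.patch_frac is None:
        in_patch = np.ones(spec.n, dtype=bool)
        patch_center = None
        patch_radius = None
    else:
        patch_center = (np.asarray(spec.patch_center, float)
                        if spec.patch_center is not None
                        else spec.mesh.vertices[0])
        dists = np.linalg.norm(pts - patch_center, axis=1)
        patch_radius = float(np.quantile(dists, spec.patch_frac))
        in_patch = dists <= patch_radius

    theta = rng.uniform(-np.pi, np.pi, size=spec.n)
    if spec.kappa >= 1e6:
        theta[in_patch] = 0.0
    elif spec.kappa > 0:
        theta[in_patch] = rng.vonmises(0.0, spec.kappa, size=int(in_patch.sum()))

    vectors = np.cos(theta)[:, None] * t1 + np.sin(theta)[:, None] * t2
    axes = AxisSet.from_vectors(pts, vectors) if spec.n else AxisSet(
        np.empty((0, 3)), np.empty((0, 3)))
    return axes, AxisFieldTruth(in_patch, patch_center, patch_radius)


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------


def make_deformation(
    kind: str,
    shape: tuple[int, int, int] = (16, 16, 16),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    *,
    angle_deg: float = 0.0,
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    factors: tuple[float, float, float] = (1.0, 1.0, 1.0),
    center: tuple[float, float, float] | None = None,
    amplitude: float = 1.0,
    max_freq: int = 1,
    steps: int = 8,
    seed: int = 0,
) -> DeformationField:
    """Construct a ground-truthed deformation field on a grid.

    Kinds: ``identity``; ``rotation`` (angle/axis about ``center``);
    ``stretch`` (positive per-axis factors about ``center``);
    ``smooth-random`` (band-limited periodic stationary velocity with the
    given amplitude, exponentiated by scaling and squaring).  The returned
    field is certified invertible (det J > 0 at every node); parameters that
    break invertibility raise :class:`InvertibilityError`.
    """
    shape = tuple(shape)
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    if center is None:
        center = origin + spacing * (np.array(shape) - 1) / 2.0
    center = np.asarray(center, float)

    if kind == "identity":
        return DeformationField.identity(shape, spacing, origin)
    if kind == "rotation":
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        phi = DeformationField.from_affine(R, center - R @ center, shape, spacing, origin)
        phi.check_invertible()
        return phi
    if kind == "stretch":
        f = np.asarray(factors, float)
        if np.any(f <= 0):
            raise InvertibilityError("stretch factors must be positive")
        A = np.diag(f)
        phi = DeformationField.from_affine(A, center - A @ center, shape, spacing, origin)
        phi.check_invertible()
        return phi
    if kind in ("smooth-random", "smooth_random"):
        v = _bandlimited_velocity(shape, spacing, origin, amplitude, max_freq, seed)
        return integrate_velocity(v, spacing, origin, steps=steps, mode="grid-wrap")
    raise ValueError(f"unknown deformation kind {kind!r}")


def _bandlimited_velocity(shape, spacing, origin, amplitude, max_freq, seed) -> np.ndarray:
    """Random periodic velocity from Fourier modes with |m_d| <= max_freq."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray(spacing) * np.array(shape)
    axes_coords = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    X = np.meshgrid(*axes_coords, indexing="ij")
    v = np.zeros((*shape, 3))
    modes = [
        (mx, my, mz)
        for mx in range(-max_freq, max_freq + 1)
        for my in range(-max_freq, max_freq + 1)
        for mz in range(-max_freq, max_freq + 1)
        if (mx, my, mz) != (0, 0, 0)
    ]
    coeff = amplitude / len(modes)
    for m in modes:
        k = 2.0 * np.pi * np.array(m) / lengths
        phase = k[0] * X[0] + k[1] * X[1] + k[2] * X[2]
        amp = rng.normal(scale=coeff, size=3)
        shift = rng.uniform(0, 2 * np.pi)
        wave = np.sin(phase + shift)
        for d in range(3):
            v[..., d] += amp[d] * wave
    return v
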