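"""Readers and writers for every external representation the pipeline touches.

Conventions used throughout the package:

* Voxel grids are indexed ``(z, y, x)`` with the channel axis last, matching
  page-major multi-page TIFF layout.  Spacing is ``(dz, dy, dx)`` in μm.
* World/geometry coordinates (axis positions, mesh vertices, deformation
  domains) are ``(x, y, z)`` in μm.  Conversions between the two orderings
  happen exactly once, where voxel measurements become geometry
  (:func:`cardax.segmentation.objects_from_labelmap`).
* Coordinates are 0-based; intervals are half-open.
* All physical quantities are carried in μm / μm² / μm³; pixel counts are
  converted at read time using the declared spacing.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

logger = logging.getLogger("cardax")

__all__ = [
    "MultiChannelStack",
    "SurfaceMesh",
    "AxisSet",
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_axes",
    "write_axes",
    "read_mesh",
    "write_mesh",
    "sign_normalize",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiChannelStack:
    """A named-channel 3D voxel grid with physical spacing.

    ``voxels`` is indexed ``(z, y, x, channel)``; ``spacing_um`` is
    ``(dz, dy, dx)`` with all entries strictly positive.  Intensities must be
    finite and non-negative.
    """

    voxels: np.ndarray
    channel_names: tuple[str, ...]
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 4:
            raise ValueError(f"voxels must be 4D (z, y, x, channel), got ndim={vox.ndim}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if len(self.channel_names) != vox.shape[3]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {vox.shape[3]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        spacing = tuple(float(s) for s in self.spacing_um)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_um must be 3 positive floats, got {self.spacing_um}")
        object.__setattr__(self, "spacing_um", spacing)
        if not np.all(np.isfinite(vox)):
            raise ValueError("intensities must be finite")
        if vox.size and vox.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.voxels[..., idx]


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangle mesh in μm: organ envelope or averaged template."""

    vertices: np.ndarray  # (V, 3) xyz μm
    faces: np.ndarray  # (F, 3) int vertex indices

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        faces = np.asarray(self.faces, dtype=int)
        if verts.ndim != 2 or verts.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
            raise ValueError("faces reference invalid vertex indices")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "faces", faces)
        if faces.size:
            tri = verts[faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            if np.any(areas <= 0):
                raise ValueError("mesh contains degenerate (zero-area) faces")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals)

    @property
    def face_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().face_normals)


def sign_normalize(vectors: np.ndarray) -> np.ndarray:
    """Apply the axial sign convention: first nonzero component >= 0.

    Axes are sign-symmetric (u and -u are the same axis); a canonical
    representative makes storage and comparison deterministic.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float)).copy()
    nonzero = v != 0
    # index of first nonzero component per row; rows of all zeros keep sign
    first = np.where(nonzero.any(axis=1), nonzero.argmax(axis=1), 0)
    lead = v[np.arange(len(v)), first]
    v[lead < 0] *= -1
    if np.asarray(vectors).ndim == 1:
        return v[0]
    return v


@dataclass(frozen=True)
class AxisSet:
    """Sign-symmetric unit division axes with positions in μm (xyz)."""

    positions: np.ndarray  # (n, 3)
    axes: np.ndarray  # (n, 3), unit, sign-normalized
    specimen: np.ndarray | None = None  # (n,) labels

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if pos.shape != axes.shape or pos.shape[1] != 3:
            raise ValueError("positions and axes must both be (n, 3)")
        norms = np.linalg.norm(axes, axis=1)
        if axes.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("axes must be unit length; use AxisSet.from_vectors")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "axes", sign_normalize(axes) if axes.size else axes)
        if self.specimen is not None:
            spec = np.asarray(self.specimen)
            if spec.shape[0] != pos.shape[0]:
                raise ValueError("specimen labels must match axis count")
            object.__setattr__(self, "specimen", spec)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def from_vectors(
        cls,
        positions: np.ndarray,
        vectors: np.ndarray,
        specimen: np.ndarray | None = None,
    ) -> "AxisSet":
        """Build an AxisSet from arbitrary-length vectors (renormalized)."""
        vec = np.atleast_2d(np.asarray(vectors, dtype=float))
        norms = np.linalg.norm(vec, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero-length axis at row(s) {bad.tolist()}")
        return cls(positions, vec / norms[:, None], specimen)


@dataclass
class RunConfig:
    """All tunable thresholds and parameters of the downstream stages.

    Defaults follow the published procedure where one is stated: a 16 μm³
    minimum object volume for the mitosis filter, a 200 px counting window,
    a 2 SD multiplier for "strong" nuclear cells and a 50-axis minimum per
    coordination region.
    """

    min_object_volume_um3: float = 16.0
    window_px: int = 200
    strong_sd_multiplier: float = 2.0
    bootstrap_replicates: int = 10_000
    region_min_axes: int = 50
    speckle_min_voxels: int = 2
    nuclei_overlap_fraction: float = 0.5
    myocyte_overlap_fraction: float = 0.5
    planar_eps: float = 0.1
    pair_lambda_angle: float = 1.0
    pair_d_max_um: float = 15.0
    pair_score_ceiling: float = 2.5
    corrected_nc_ratio: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_object_volume_um3 < 0:
            raise ValueError("min_object_volume_um3 must be >= 0")
        if self.window_px <= 0 or self.region_min_axes < 1:
            raise ValueError("window_px and region_min_axes must be positive")
        if self.bootstrap_replicates < 100:
            raise ValueError("bootstrap_replicates must be >= 100")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    spacing_um: tuple[float, float, float],
    channel_names: tuple[str, ...] | list[str],
) -> MultiChannelStack:
    """Read a multi-page TIFF into a :class:`MultiChannelStack`.

    Pages are z-major with the channel index varying fastest
    (page ``p`` holds slice ``p // C``, channel ``p % C``).  The page count
    must be divisible by the declared channel count.
    """
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected grayscale pages, got shape {pages.shape}")
    n_channels = len(channel_names)
    if n_channels < 1 or pages.shape[0] % n_channels != 0:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by channel count {n_channels}"
        )
    nz = pages.shape[0] // n_channels
    vox = pages.reshape(nz, n_channels, *pages.shape[1:])
    vox = np.moveaxis(vox, 1, -1)
    logger.info("read_stack %s: shape=%s channels=%s", path, vox.shape, tuple(channel_names))
    return MultiChannelStack(vox, tuple(channel_names), spacing_um)


def write_stack(stack: MultiChannelStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (inverse of :func:`read_stack`)."""
    vox = np.moveaxis(stack.voxels, -1, 1)  # (z, c, y, x)
    pages = vox.reshape(-1, *vox.shape[2:])
    tifffile.imwrite(str(path), pages, photometric="minisblack")


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------

_AXIS_COLUMNS = ["specimen", "x", "y", "z", "ux", "uy", "uz"]


def read_axes(path: str | Path) -> AxisSet:
    """Read a division-axis table (CSV: specimen, x, y, z, ux, uy, uz).

    Axes are renormalized to unit length and sign-normalized; a zero-length
    axis row is rejected with its row index.
    """
    df = pd.read_csv(path)
    missing = [c for c in _AXIS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"axis CSV missing columns {missing}")
    positions = df[["x", "y", "z"]].to_numpy(dtype=float)
    vectors = df[["ux", "uy", "uz"]].to_numpy(dtype=float)
    return AxisSet.from_vectors(positions, vectors, specimen=df["specimen"].to_numpy())


def write_axes(axes: AxisSet, path: str | Path) -> None:
    specimen = (
        axes.specimen if axes.specimen is not None else np.zeros(len(axes), dtype=int)
    )
    df = pd.DataFrame(
        {
            "specimen": specimen,
            "x": axes.positions[:, 0],
            "y": axes.positions[:, 1],
            "z": axes.positions[:, 2],
            "ux": axes.axes[:, 0],
            "uy": axes.axes[:, 1],
            "uz": axes.axes[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an OFF or PLY mesh."""
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return SurfaceMesh.from_trimesh(mesh)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write an ASCII OFF/PLY mesh (format chosen by extension)."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif path.suffix.lower() == ".off":
        data = tm.export(file_type="off")
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use .off or .ply)")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
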