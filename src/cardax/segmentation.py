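"""Object detection and measurement: threshold → connected components → size filter.

The proliferation readout follows the published procedure: the mitosis-marker
(PH3) channel is thresholded and segmented by connected-component analysis,
objects under a minimum volume of 16 μm³ are discarded as non-specific
signal, objects are restricted to the myocyte-marker mask, and the count is
normalized by a nucleus-density extrapolation from a 200×200 px counting
window to the full myocardial area.

Connectivity is fixed at 26 (3D) / 8 (2D): the permissive choice merges
diffraction-split nuclei.  "Under a minimum size" is read strictly: objects
with volume < threshold are removed, the boundary case is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage import draw as skdraw
from skimage import filters as skfilters
from skimage import measure as skmeasure

from .io_formats import MultiChannelStack

__all__ = [
    "LabelMap",
    "SegmentedObject",
    "ShapeMetrics",
    "segment_channel",
    "label_image",
    "objects_from_labelmap",
    "filter_by_volume",
    "restrict_to_mask",
    "mitotic_index",
    "region_area",
    "shape_metrics",
    "cell_area_from_contours",
]


@dataclass(frozen=True)
class LabelMap:
    """Integer label grid (0 = background) with its physical spacing.

    Labels are consecutive positive integers; each label's voxel set is one
    26-connected (3D) or 8-connected (2D) component.
    """

    labels: np.ndarray
    spacing_um: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim not in (2, 3):
            raise ValueError("label grid must be 2D or 3D")
        spacing = tuple(float(s) for s in self.spacing_um)
        if len(spacing) != labels.ndim or any(s <= 0 for s in spacing):
            raise ValueError("spacing must have one positive entry per grid axis")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing_um", spacing)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing_um))


@dataclass(frozen=True)
class SegmentedObject:
    """One labelled component with physical measurements.

    ``centroid_um`` is in world (x, y, z) order — for 2D maps, (x, y).
    ``volume_um3`` is the voxel count times the voxel volume (an area in μm²
    for 2D maps).
    """

    label: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, ...]
    bbox: tuple[int, ...]


@dataclass(frozen=True)
class ShapeMetrics:
    aspect_ratio: float  # minor/major axis length of the mask, in (0, 1]
    nuclei_count: int


def label_image(foreground: np.ndarray, spacing_um) -> LabelMap:
    """Label a binary image with the package's fixed connectivity (26/8)."""
    fg = np.asarray(foreground).astype(bool)
    labels = skmeasure.label(fg, connectivity=fg.ndim)
    return LabelMap(labels.astype(np.int32), tuple(spacing_um))


def segment_channel(
    stack: MultiChannelStack,
    channel: str,
    threshold: float | str = "otsu",
    invert: bool = False,
) -> LabelMap:
    """Threshold one channel and label connected foreground components.

    ``threshold`` is an absolute intensity, or ``"otsu"`` for the automatic
    between-class-variance criterion.  With ``invert`` the channel is
    intensity-inverted before thresholding (dark-foreground images).  An
    empty foreground yields a valid empty LabelMap.
    """
    img = np.asarray(stack.channel(channel), dtype=float)
    if invert:
        img = img.max() - img
    if threshold == "otsu":
        thr = float(skfilters.threshold_otsu(img)) if np.ptp(img) > 0 else np.inf
    else:
        thr = float(threshold)
    return label_image(img > thr, stack.spacing_um)


def objects_from_labelmap(label_map: LabelMap) -> list[SegmentedObject]:
    """Measure every labelled component (volumes and centroids in μm)."""
    spacing = label_map.spacing_um
    props = skmeasure.regionprops(label_map.labels, spacing=spacing)
    objects = []
    for p in props:
        centroid = tuple(float(c) for c in p.centroid[::-1])  # (z,y,x)->(x,y,z)
        objects.append(
            SegmentedObject(
                label=int(p.label),
                voxel_count=int(p.num_pixels),
                volume_um3=float(p.num_pixels) * label_map.voxel_volume,
                centroid_um=centroid,
                bbox=tuple(int(b) for b in p.bbox),
            )
        )
    return objects


def filter_by_volume(
    objects: list[SegmentedObject], min_volume_um3: float
) -> list[SegmentedObject]:
    """Drop objects strictly under the minimum physical volume (order kept)."""
    if min_volume_um3 < 0:
        raise ValueError("min_volume_um3 must be >= 0")
    return [o for o in objects if o.volume_um3 >= min_volume_um3]


def restrict_to_mask(
    label_map: LabelMap,
    objects: list[SegmentedObject],
    mask: np.ndarray,
    min_overlap: float = 0.5,
) -> list[SegmentedObject]:
    """Keep objects with at least ``min_overlap`` of their voxels inside ``mask``.

    Used to count a mitotic figure as a cardiomyocyte mitosis only when it
    lies (mostly) within the myocyte-marker mask.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != label_map.labels.shape:
        raise ValueError("mask shape must match the label grid")
    n = label_map.n_objects
    if n == 0:
        return []
    total = np.bincount(label_map.labels.ravel(), minlength=n + 1)
    inside = np.bincount(label_map.labels[mask].ravel(), minlength=n + 1)
    keep = {
        lbl for lbl in range(1, n + 1)
        if total[lbl] and inside[lbl] / total[lbl] >= min_overlap
    }
    return [o for o in objects if o.label in keep]


def mitotic_index(
    n_mitotic: int,
    window_nucleus_count: int,
    window_area_px: float,
    myocardial_area_px: float,
) -> float:
    """Mitotic index (%) by density extrapolation.

    The total nucleus count is estimated as
    ``window_nucleus_count × myocardial_area_px / window_area_px`` — the
    counting window and the myocardial outline must span the same z-extent —
    and the index is ``100 × n_mitotic / total``.
    """
    if window_nucleus_count <= 0:
        raise ZeroDivisionError("window nucleus count must be positive")
    if window_area_px <= 0 or myocardial_area_px <= 0:
        raise ZeroDivisionError("window and myocardial areas must be positive")
    total_nuclei = window_nucleus_count * (myocardial_area_px / window_area_px)
    return 100.0 * n_mitotic / total_nuclei


def region_area(
    mask_polygon: np.ndarray,
    label_map: LabelMap,
    speckle_min_voxels: int = 2,
) -> tuple[float, LabelMap]:
    """Tissue area inside a polygonal mask, excluding small speckles.

    ``mask_polygon`` is an (m, 2) array of (x, y) vertices in pixel
    coordinates on a 2D label map.  Components are re-measured inside the
    polygon; those under ``speckle_min_voxels`` pixels (blood speckles) are
    excluded.  Returns the retained area in μm² and the tissue-only LabelMap.
    """
    if label_map.labels.ndim != 2:
        raise ValueError("region_area operates on 2D label maps")
    poly = Polygon(np.asarray(mask_polygon, dtype=float))
    if not poly.is_valid:
        raise ValueError("mask polygon is invalid (self-intersecting?)")
    verts = np.asarray(mask_polygon, dtype=float)
    mask = skdraw.polygon2mask(label_map.labels.shape, verts[:, ::-1])  # (x,y)->(row,col)
    inside = np.where(mask, label_map.labels, 0)
    counts = np.bincount(inside.ravel())
    counts[0] = 0
    keep = np.flatnonzero(counts >= speckle_min_voxels)
    tissue = np.where(np.isin(inside, keep), inside, 0)
    area = float(tissue.astype(bool).sum()) * label_map.voxel_volume
    return area, LabelMap(tissue, label_map.spacing_um)


def shape_metrics(
    cell_mask: np.ndarray,
    nuclei_map: LabelMap | None = None,
    spacing_um: tuple[float, float] = (1.0, 1.0),
    overlap_fraction: float = 0.5,
) -> ShapeMetrics:
    """Aspect ratio (minor/major principal axis) and nuclei-per-cell count.

    A nucleus counts as belonging to the cell when at least
    ``overlap_fraction`` of its pixels fall inside the cell mask.
    """
    mask = np.asarray(cell_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    props = skmeasure.regionprops(mask.astype(np.uint8), spacing=spacing_um)[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    aspect = float(minor / major) if major > 0 else 1.0

    nuclei_count = 0
    if nuclei_map is not None:
        n = nuclei_map.n_objects
        if nuclei_map.labels.shape != mask.shape:
            raise ValueError("nuclei map shape must match the cell mask")
        if n:
            total = np.bincount(nuclei_map.labels.ravel(), minlength=n + 1)
            inside = np.bincount(nuclei_map.labels[mask].ravel(), minlength=n + 1)
            nuclei_count = int(
                sum(1 for lbl in range(1, n + 1)
                    if total[lbl] and inside[lbl] / total[lbl] >= overlap_fraction)
            )
    return ShapeMetrics(aspect_ratio=aspect, nuclei_count=nuclei_count)


def cell_area_from_contours(
    contours: list[np.ndarray],
    spacing_um: tuple[float, float] = (1.0, 1.0),
) -> list[float]:
    """Areas (μm²) of closed planar cell contours.

    Each contour is an (m ≥ 3, 2) vertex array in pixel coordinates, read as
    a closed ring (the closing edge is implicit; a repeated last vertex is
    accepted).  Contours with fewer than three distinct vertices (open or
    degenerate) or with self-intersections are rejected.  The area is the
    shoelace area scaled by the pixel area, independent of orientation.
    """
    dx, dy = spacing_um
    areas = []
    for i, verts in enumerate(contours):
        v = np.asarray(verts, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"contour {i}: expected (m, 2) vertices")
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(np.unique(v, axis=0)) < 3:
            raise ValueError(f"contour {i}: open or degenerate (need >= 3 distinct vertices)")
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError(f"contour {i}: invalid polygon (self-intersecting?)")
        areas.append(float(poly.area) * dx * dy)
    return areas
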