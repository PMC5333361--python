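"""Nuclear vs cytoplasmic protein quantification and reporter mosaicism.

Per cell, the protein-of-interest (PI) channel yields two average
intensities: PItot over the whole segmented cell and PInucl over its
nucleus.  The nuclear/cytoplasmic ratio is scored verbatim as

    N/C = PInucl / (PItot − PInucl)

which is well defined only while PItot > PInucl; nuclear-saturated cells are
flagged rather than crashed on.  Because PItot is the whole-cell *mean*,
PItot − PInucl is proportional to (cytoplasmic mean − nuclear mean) rather
than being the cytoplasmic mean itself; an area-weighted corrected variant
(``corrected=True``) divides PInucl by the true cytoplasmic mean instead and
stays defined for nuclear-enriched cells.  The verbatim form is the default.

"Strong" cells are cells whose PInucl exceeds the control-population mean by
more than m standard deviations (m = 2 by default).  Reporter mosaicism
(e.g. GFP-high vs Tomato-high recombination outcomes) is classified by a
two-cluster k-means partition of per-nucleus two-channel signals, measured
in a box around each nucleus excluding the nucleus itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import MultiChannelStack

__all__ = [
    "CellIntensityRecord",
    "NCResult",
    "MosaicResult",
    "measure_cell",
    "measure_cells",
    "nc_ratio",
    "strong_cells",
    "mosaic_classify",
    "measure_reporter_signals",
    "best_focus_slice",
    "z_project_sum",
    "read_cell_records",
    "write_cell_records",
]


@dataclass(frozen=True)
class CellIntensityRecord:
    """Average intensities over a cell and its nucleus, with areas in μm²/μm³."""

    cell_id: int
    pi_tot: float  # total intensity / cell area
    pi_nucl: float  # total nuclear intensity / nuclear area
    cell_area: float
    nuclear_area: float

    def __post_init__(self) -> None:
        if self.cell_area <= 0 or self.nuclear_area <= 0:
            raise ValueError("areas must be positive")
        if self.nuclear_area > self.cell_area * (1 + 1e-9):
            raise ValueError("nuclear area cannot exceed cell area")
        if self.pi_tot < 0 or self.pi_nucl < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class NCResult:
    ratio: float  # nan when saturated
    saturated: bool
    corrected: bool = False


@dataclass(frozen=True)
class MosaicResult:
    """Two-cluster reporter partition; class 'A' has the higher first-channel centroid."""

    classes: np.ndarray  # (n,) 'A' / 'B'
    fractions: tuple[float, float]  # (frac_A, frac_B), summing to 1
    centroids: np.ndarray  # (2, 2), row 0 = class A
    degenerate: bool = False


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def best_focus_slice(stack: MultiChannelStack, nuclei_channel: str = "nuclei") -> int:
    """Best in-focus z-slice: the slice maximizing nuclear-channel variance."""
    img = stack.channel(nuclei_channel)
    return int(np.argmax(img.reshape(img.shape[0], -1).var(axis=1)))


def z_project_sum(stack: MultiChannelStack, channel: str) -> np.ndarray:
    """Sum z-projection of one channel (the in-vitro measurement mode)."""
    return np.asarray(stack.channel(channel), dtype=float).sum(axis=0)


# ---------------------------------------------------------------------------
# per-cell measurement
# ---------------------------------------------------------------------------


def measure_cell(
    intensity: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    voxel_volume: float = 1.0,
    cell_id: int = 0,
) -> CellIntensityRecord:
    """Average PI intensity over a cell mask and its nucleus mask.

    The nucleus mask must be contained in the cell mask and both must be
    non-empty.  Masking implements the multiplication of the PI channel with
    the binary segmentation images.
    """
    img = np.asarray(intensity, dtype=float)
    cell = np.asarray(cell_mask).astype(bool)
    nuc = np.asarray(nucleus_mask).astype(bool)
    if img.shape != cell.shape or img.shape != nuc.shape:
        raise ValueError("intensity and masks must share one shape")
    if not cell.any() or not nuc.any():
        raise ValueError("empty cell or nucleus mask")
    if np.any(nuc & ~cell):
        raise ValueError("nucleus mask must be contained in the cell mask")
    return CellIntensityRecord(
        cell_id=cell_id,
        pi_tot=float(img[cell].mean()),
        pi_nucl=float(img[nuc].mean()),
        cell_area=float(cell.sum()) * voxel_volume,
        nuclear_area=float(nuc.sum()) * voxel_volume,
    )


def measure_cells(
    intensity: np.ndarray,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    voxel_volume: float = 1.0,
) -> list[CellIntensityRecord]:
    """Measure every cell id present in both label grids (matching ids)."""
    ids = sorted(set(np.unique(cell_labels)) & set(np.unique(nucleus_labels)) - {0})
    records = []
    for i in ids:
        cell = cell_labels == i
        nuc = (nucleus_labels == i) & cell  # clip nuclei to their cell
        if not nuc.any():
            continue
        records.append(measure_cell(intensity, cell, nuc, voxel_volume, cell_id=int(i)))
    return records


def nc_ratio(record: CellIntensityRecord, corrected: bool = False) -> NCResult:
    """Nuclear/cytoplasmic ratio of one cell.

    Verbatim form: PInucl / (PItot − PInucl); saturated (flagged, ratio NaN)
    when PItot ≤ PInucl.  Corrected form: PInucl divided by the area-weighted
    cytoplasmic mean (T_cell − T_nucl) / (A_cell − A_nucl).
    """
    if record.pi_nucl == 0:
        return NCResult(0.0, saturated=False, corrected=corrected)
    if corrected:
        cyto_area = record.cell_area - record.nuclear_area
        if cyto_area <= 0:
            return NCResult(np.nan, saturated=True, corrected=True)
        cyto_mean = (
            record.pi_tot * record.cell_area - record.pi_nucl * record.nuclear_area
        ) / cyto_area
        if cyto_mean <= 0:
            return NCResult(np.nan, saturated=True, corrected=True)
        return NCResult(float(record.pi_nucl / cyto_mean), saturated=False, corrected=True)
    if record.pi_tot <= record.pi_nucl:
        return NCResult(np.nan, saturated=True)
    return NCResult(float(record.pi_nucl / (record.pi_tot - record.pi_nucl)),
                    saturated=False)


def strong_cells(
    records: list[CellIntensityRecord],
    control_records: list[CellIntensityRecord],
    m: float = 2.0,
) -> tuple[np.ndarray, float, float]:
    """Classify cells as "strong" nuclear against a control population.

    Threshold = mean(control PInucl) + m × SD(control PInucl); a cell is
    strong iff its PInucl strictly exceeds the threshold.  Returns the
    per-cell booleans, the strong percentage and the threshold.  At least two
    control records are required for the SD to be defined.
    """
    if len(control_records) < 2:
        raise ValueError("need >= 2 control records to define an SD")
    control = np.array([r.pi_nucl for r in control_records])
    threshold = float(control.mean() + m * control.std(ddof=1))
    values = np.array([r.pi_nucl for r in records])
    strong = values > threshold
    pct = 100.0 * strong.mean() if len(values) else 0.0
    return strong, float(pct), threshold


# ---------------------------------------------------------------------------
# mosaicism
# ---------------------------------------------------------------------------


def measure_reporter_signals(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    nucleus_labels: np.ndarray,
    box_half_width_factor: float = 2.0,
) -> pd.DataFrame:
    """Mean two-channel reporter signal in a box around each nucleus.

    The box half-width is ``box_half_width_factor`` times the nucleus'
    equivalent radius; the nucleus' own pixels are excluded.  Returns a frame
    with columns nucleus_id, signal_a, signal_b.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    labels = np.asarray(nucleus_labels)
    if a.shape != labels.shape or b.shape != labels.shape:
        raise ValueError("channels and labels must share one shape")
    rows = []
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        idx = np.argwhere(labels == lbl)
        count = len(idx)
        radius = (count * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) if labels.ndim == 3 \
            else np.sqrt(count / np.pi)
        half = max(int(np.ceil(box_half_width_factor * radius)), 1)
        center = idx.mean(axis=0).round().astype(int)
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, s))
            for c, s in zip(center, labels.shape)
        )
        box = np.ones_like(labels[sl], dtype=bool)
        box &= labels[sl] != lbl
        if not box.any():
            continue
        rows.append((int(lbl), float(a[sl][box].mean()), float(b[sl][box].mean())))
    return pd.DataFrame(rows, columns=["nucleus_id", "signal_a", "signal_b"])


def mosaic_classify(signals: np.ndarray, seed: int = 0) -> MosaicResult:
    """Two-cluster partition of (channel-A, channel-B) signal pairs.

    Initialized deterministically from the points at extreme first-channel
    values, then refined by standard k-means; the seed only breaks exact
    ties.  Classes are labelled so 'A' has the greater first-channel
    centroid.  All-identical points are rejected; a vanishing centroid
    separation yields a degenerate-partition warning.
    """
    pts = np.asarray(signals, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("signals must be (n >= 2, 2)")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical: no two-cluster partition exists")
    init = np.vstack([pts[np.argmax(pts[:, 0])], pts[np.argmin(pts[:, 0])]])
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=seed).fit(pts)
    centroids = km.cluster_centers_
    order = np.argsort(-centroids[:, 0])  # class A = higher first channel
    centroids = centroids[order]
    remap = np.empty(2, dtype=int)
    remap[order] = [0, 1]
    assignment = remap[km.labels_]
    classes = np.where(assignment == 0, "A", "B")
    frac_a = float(np.mean(assignment == 0))
    degenerate = bool(np.linalg.norm(centroids[0] - centroids[1]) < 1e-9)
    if degenerate:
        warnings.warn("degenerate two-cluster partition: coincident centroids",
                      stacklevel=2)
    return MosaicResult(classes, (frac_a, 1.0 - frac_a), centroids, degenerate)


# ---------------------------------------------------------------------------
# per-cell CSV
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ["cell_id", "pi_tot", "pi_nucl", "cell_area", "nuclear_area"]


def write_cell_records(records: list[CellIntensityRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=_CELL_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_cell_records(path) -> list[CellIntensityRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell CSV missing columns {missing}")
    return [
        CellIntensityRecord(int(r.cell_id), float(r.pi_tot), float(r.pi_nucl),
                            float(r.cell_area), float(r.nuclear_area))
        for r in df.itertuples()
    ]
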