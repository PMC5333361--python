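# cardax

Quantitative 3D image analysis of **oriented cell division** in heart
tissue, for developmental biologists and image analysts who need the full
chain from multi-channel confocal stacks to calibrated coordination
statistics: segmentation with physical size filters, mitotic-index
estimation, nuclear/cytoplasmic protein quantification, reporter-mosaicism
classification, sister-nucleus pairing at cytokinetic bridges, diffeomorphic
transport of axes onto an average template, and orientation-tensor
statistics with bootstrap significance thresholds. A ground-truthed
synthetic-scene generator makes every stage testable without any imaging
data.

## The statistic at the core

For sign-symmetric unit division axes u₁…uₙ (each joining two sister-nucleus
centroids) the orientation tensor

```
T = (1/n) Σᵢ uᵢuᵢᵀ
```

has unit trace; its largest eigenvalue **E1** measures axial coordination
(planar isotropy E1 = 0.5, perfect alignment E1 = 1). Coordination in a
region of n axes is significant at the 5% level when E1 exceeds **E1(5%)**,
the 95th percentile of E1 over bootstrap replicates of n uniformly oriented
tangent-plane axes. The core region of a template is the geodesic disc with
the highest E1 among those holding at least 50 axes; contour maps report
E1/E1(5%) for every disc containing the core. When axes from several
specimens are pooled, positions map through a diffeomorphism φ onto the
template while directions rotate by the **polar part** of the Jacobian of φ
— the stretch factor is discarded so that transport cannot spuriously
improve axial correlation.

## Worked example

Plant a coordinated patch (concentration κ = 20, 20% of the surface) on a
spherical template, then recover it with the region scan:

```python
import numpy as np
import trimesh

from cardax import polarity_stats as ps, synthetic_data as sd
from cardax.io_formats import SurfaceMesh

template = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=2))
axes, truth = sd.make_axis_field(
    sd.AxisFieldSpec(mesh=template, n=500, kappa=20.0, patch_frac=0.2, seed=42))

stats = ps.orientation_stats(axes)
print(f"n = {stats.n} axes, global E1 = {stats.e1:.3f}")

table = ps.BootstrapThresholdTable(B=10_000, seed=0)
scan = ps.scan_regions(axes, template, radii=[0.5, 0.7, 0.9, 1.1],
                       min_axes=50, thresholds=table)
core = scan.core
print(f"core region: vertex {core.center_vertex}, radius {core.radius}, "
      f"n = {core.n}")
print(f"core E1 = {core.e1:.3f}, E1(5%) = {core.threshold:.3f}, "
      f"contour value = {core.ratio:.2f}")
centroid = axes.positions[core.member_idx].mean(axis=0)
inside = np.linalg.norm(centroid - truth.patch_center) <= truth.patch_radius
print(f"core centroid inside the planted patch: {inside}")
```

Output:

```
n = 500 axes, global E1 = 0.419
core region: vertex 42, radius 0.7, n = 66
core E1 = 0.861, E1(5%) = 0.606, contour value = 1.42
core centroid inside the planted patch: True
```

Globally the field looks almost isotropic (E1 = 0.419, barely above the 3D
floor of 1/3) because 80% of the axes are random — but the scan localizes a
66-axis disc whose E1 = 0.861 exceeds its size-matched null threshold by
42%, and the disc sits inside the planted patch.

A command-line layer covers the common batch operations
(`cardax simulate | segment | mitotic-index | cell-size | localize | mosaic |
axes | template | transport | polarity | qpcr`); run `cardax --help`.

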