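# Methods

`cardax` reimplements, as a tested and reusable pipeline, the quantitative
machinery used to analyse oriented cell division, proliferation, cell size
and nuclear/cytoplasmic protein localization in 3D fluorescence images of
embryonic heart tissue. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Orientation statistics

A division axis is the sign-symmetric unit vector joining the centroids of
two sister nuclei. For axes u₁…uₙ the orientation tensor is

    T = (1/n) Σ uᵢuᵢᵀ,

symmetric positive-semidefinite with trace 1; its sorted eigenvalues sum to
one and the largest, E1, measures axial coordination. Because uuᵀ is even in
u, every statistic is invariant to the arbitrary sign of an axis. For axes
confined to a plane the eigenvalues are ((1 ± R₂)/2, 0), where R₂ is the
resultant length of the doubled in-plane angles, so E1 runs from 0.5
(planar isotropy) to 1 (perfect alignment); free 3D axes have isotropic
value 1/3.

Significance is judged against a tangent-plane isotropic null. E1(5%) for a
region of n axes is the 95th percentile (linear interpolation between order
statistics) of E1 over B bootstrap replicates of n uniformly oriented
in-plane axes; B defaults to 10,000. For in-plane axes the null is simulated
directly on angles, which makes the threshold a function of n alone. A
position-aware variant draws uniform directions in the tangent planes of
supplied surface normals instead; on a flat template the two coincide (a
property the tests check). Whether the original procedure resampled
observed directions or drew fresh uniform ones is not recoverable; the
fresh-uniform null is the default and the normals-based variant is exposed.
For region scans, thresholds are simulated at pivot sizes and interpolated
linearly in 1/√n, the scale on which E1 − ½ contracts under the null.

Regions are geodesic discs grown from every template vertex over a
user-supplied radius list, with geodesic distances computed by Dijkstra on
the mesh edge graph. The core region is the disc with the highest E1 among
those containing at least `region_min_axes` axes (default 50). The contour
map lists every disc that geodesically contains the core disc and whose E1
exceeds its E1(5%), with contour value E1/E1(5%); a value above 1 marks
significant coordination at the 5% level. Disc regions were chosen because
they are rotation-invariant and add a single parameter (the radius list);
the region family used on the original heart template is not documented.

## Diffeomorphic transport

Axes measured on different specimens are pooled on a common template. The
template is built from corresponded envelopes by generalized Procrustes
analysis — iterated rigid (no scaling) alignment to the running vertex-wise
mean until the mean moves less than a tolerance — which preserves all
between-specimen shape variation in the residuals. Deformations are
displacement fields u on a regular grid, φ(x) = x + u(x), interpolated
trilinearly; diffeomorphisms are generated from stationary velocity fields
by scaling and squaring, φ = exp(v), with invertibility certified by
det J > 0 at every node. Variational template matching over a deformation
group is deliberately not implemented: every downstream statistic depends
only on having *some* valid φ with a Jacobian, and the desk-scale stand-ins
preserve every testable transport property.

Axis positions map through φ; axis directions rotate by the polar
(rotational) factor R of the Jacobian J = RS at the axis midpoint, computed
by SVD with the determinant constraint (det J > 0 forces det R = +1).
Discarding the stretch factor S is the load-bearing choice: a pure stretch
then transports every direction unchanged, so no deformation can spuriously
tighten or loosen the axial distribution (verified to 1e−12 in the tests).
As an extra guard, E1(5%) can be computed before and after transport and
the larger threshold retained. Jacobians use central finite differences at
native grid spacing (second order, no extra parameters); boundary nodes
fall back to one-sided differences and are flagged.

## Segmentation and proliferation

Objects are detected by thresholding a channel (fixed value, or Otsu's
criterion when none is configured — the original thresholds are not
documented, so they are parameters here, not constants) and labelling
connected components. Connectivity is fixed at 26 (3D) / 8 (2D); the
permissive choice merges diffraction-split nuclei. Mitotic figures are
filtered at a minimum physical volume of 16 μm³, read strictly: objects
with volume < 16 μm³ are removed, the boundary case retained. A mitosis
counts as a cardiomyocyte mitosis when at least half of its voxels fall in
the myocyte-marker mask (the published counting states no overlap rule).
The mitotic index extrapolates a nucleus count from a 200 × 200 px window
spanning the full z-extent to the outlined myocardial area:
index = 100 · n_mitotic / (window_count · area / window_area). No edge
correction is applied to the window density. Tissue area inside a polygonal
mask excludes components under a configurable speckle size (blood
speckles); cell areas come from the shoelace formula on supplied closed
contours; the aspect ratio is minor/major principal axis length of an
object mask.

## Protein localization and mosaicism

Per cell, PItot is the mean protein intensity over the segmented cell and
PInucl the mean over its nucleus. The nuclear/cytoplasmic ratio is scored
verbatim as PInucl/(PItot − PInucl). Note that PItot − PInucl is
proportional to (cytoplasmic mean − nuclear mean), not the cytoplasmic
mean, so the verbatim ratio is only defined while the nuclear mean is below
the whole-cell mean — equivalently while the nuclear signal fraction is
below the nucleus' volume fraction of the cell. Nuclear-saturated cells are
flagged, not crashed on. An area-weighted corrected variant divides PInucl
by the true cytoplasmic mean (T_cell − T_nucl)/(A_cell − A_nucl) and stays
defined for nuclear-enriched cells; it is off by default (reproduce first,
improve optionally) but is the form used for translocation-series
benchmarks, since any renderable nucleus/cytoplasm geometry leaves the
verbatim formula's domain partway through a 0.1→0.9 nuclear-fraction sweep
(the verbatim form is additionally benchmarked over its valid sub-range).
"Strong" cells exceed the control-population mean PInucl by more than m
standard deviations (m = 2); on a null treatment with Gaussian controls
this tags the upper ≈2.28% tail, which the tests verify. In-vivo
measurements use the z-slice maximizing nuclear-channel variance (the
original best-focus criterion is unstated); in-vitro measurements sum over
z. Reporter mosaicism is classified by k-means with k = 2 on per-nucleus
(channel-A, channel-B) means measured in a box of half-width two nuclear
radii around each nucleus, excluding the nucleus itself (the original box
size is unstated). The partition is initialized from the two points at
extreme first-channel values, so the result is deterministic; the seed only
breaks exact ties; classes are labelled by first-channel centroid order.

## Sister pairing

Cytokinetic-bridge endpoints are the extremal points of the component's
longest 26-connected path (double breadth-first sweep). Candidate nuclei
lie within d_max (default 15 μm) of an endpoint; a cross-endpoint pair
(i, j) scores

    (dᵢ + dⱼ)/d_max + λ·(1 − |cos θ|),

with θ the angle between the bridge axis and the centroid-joining axis and
λ = 1 by default. Pairs are accepted greedily in ascending score order,
each nucleus at most once, below a score ceiling (default 2.5). The exact
form of the original scoring function is not published; this additive form
is declared, configurable, and validated only against synthetic ground
truth, never against published numbers.

## Small statistics

Relative expression from qPCR cycle thresholds is R = 2^(Ct_control −
Ct_target). Outliers are excluded by the modified Thompson Tau procedure:
iteratively test the single most extreme point against τ·SD, with
τ = t_(α/2,n−2)(n−1)/(√n·√(n−2+t²)), removing one point per iteration until
convergence (α = 0.05). ANOVA, Tukey HSD, Kolmogorov–Smirnov, Wilcoxon and
Mann–Whitney are thin pass-throughs to scipy.

## Synthetic scenes: what they emulate and what they do not

The generator renders nuclei as Gaussian blobs whose half-maximum
isosurface is a sphere of the planted radius (σ = r/√(2 ln 2)), cells as
concentric spheres twice the nuclear radius, protein split between the
compartments by the planted nuclear fraction, mitotic nuclei as an
independent Bernoulli draw, bridges as capsules spanning the middle half of
planted sister-pair segments, and reporters as a two-component bivariate
Gaussian mixture stamped around each nucleus. Poisson noise precedes
Gaussian read noise (conventional camera model). Nucleus centres keep a
minimum separation of 1.5 × the radius sum so half-maximum supports stay
disjoint under 26-connectivity; sister nuclei are exempt (they sit side by
side at cytokinesis) and only must not overlap. Axis fields live in mesh
tangent planes with in-plane angles from a von Mises distribution
(sign-symmetrized by axial storage; κ = 0 uniform, κ ≥ 1e6 exactly the
bias); a full Fisher–Bingham model is unnecessary because the statistics
only see tangent-plane components. Every generator is a pure function of
(spec, seed).

These scenes deliberately omit point-spread blur, sarcomere texture,
intensity inhomogeneity, touching nuclei and segmentation errors that real
confocal stacks contain. Passing benchmarks therefore certify the
*statistical machinery* — calibration of the null, invariance under
transport, exact recovery when detection is easy — not robustness of
thresholding to difficult real images, which remains parameter tuning per
dataset. No acquisition noise statistics were available to copy, so noise
levels are swept in tests rather than fixed.

## Benchmark problem sizes and defaults

Benchmarks run at: 10,000 axes for isotropic-limit checks; 1,000 null
fields of 50 axes for type-I calibration (expected rate inside the 95%
binomial band around 5%); 200 seeded runs for recovery of a κ = 20 patch
covering 20% of a 162-vertex spherical template (≥95% required); 1,000
random determinant-positive matrices for the polar oracle (1e−6); a 64³
grid for the spectral Jacobian oracle (1e−4); 2,000 nuclei at 2% mitotic
fraction for index recovery (within the Binomial 95% interval); 10,000
cells for the strong-cell null rate; 1,000 nuclei at 10-SD separation and
0.7/0.3 mixing for mosaicism (±2%); ten noisy spheres for template
averaging (radial RMS ≈ σ/√10, ±20%). Key defaults: 16 μm³ minimum object
volume, 200 px counting window, 2 SD strong-cell multiplier, 50-axis
minimum region size, B = 10,000 bootstrap replicates, λ = 1 and
d_max = 15 μm for pairing, planar-component cutoff ε = 0.1 for projection.

## Known limitations

Geodesic distances follow mesh edges and overestimate true surface
distances by the graph stretch factor (a few percent on an icosphere);
region membership is assigned via each axis' nearest vertex. The
interpolated threshold table is slightly conservative on strongly curved
regions, where the attainable E1 of tangent-plane fields is itself bounded
below 1 by normal dispersion. Scaling-and-squaring accuracy is first order
in the scaled step; the default of 8 squarings suits the smooth, small
deformations used here and can be raised where 1e−6-level agreement with a
matrix exponential is needed. Template averaging requires pre-corresponded
meshes; establishing correspondence is out of scope.
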