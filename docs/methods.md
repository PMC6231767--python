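# Methods

This note records the models, conventions and numerical choices behind
`embryocarpet`, in the order the pipeline runs.

## Coordinate conventions

Volumes are arrays in (z, y, x) order with per-axis voxel spacing in µm
(default 1.0 × 0.24 × 0.24 µm, the confocal sampling the pipeline targets).
Point clouds use cartesian (x, y, z) columns in µm, one point per masked
voxel at its physical center.  After alignment the AP axis is +z and the
dorsal reference lies in the +y half-plane; cylindrical θ is measured from
the dorsal meridian (θ = 0 dorsal, θ = π ventral), increasing toward the
embryo's left.  The handedness is a package convention — biological
reporting only fixes the dorsal/ventral meridians, and all folded angular
positions (0–180°) are invariant to it.  Times are minutes relative to the
onset of germband extension; positions along the egg are % egg length with
0% at the posterior pole.

## Segmentation and layer peeling

Each frame is thresholded with Otsu's criterion; in time series the
threshold is exponentially smoothed, `thr_t = 0.3·otsu_t + 0.7·thr_{t-1}`.
The estimator and smoothing weight are package choices — "time-adaptive"
thresholding admits many realizations, and this one is parameter-light and
demonstrably reduces frame-to-frame threshold flicker on static scenes
(asserted by a test).  After thresholding, all but the largest 26-connected
component are discarded and interior holes (the dim yolk) are filled using
the 26-connected background complement, which prevents diagonal leaks out
of cavities.  A segmentation whose foreground touches more than half of the
volume border triggers a warning (threshold failure), an empty foreground
is an error.

Erosion by a physical depth r is implemented as thresholding the
anisotropy-aware Euclidean distance transform (`d > r` with
`sampling = voxel_spacing`).  This is exactly morphological erosion by the
ball of radius r µm — an ellipsoidal structuring element in voxel units —
but runs in linear time at 200³.  The volume border does not erode the mask
(the EDT sees no background outside the array), matching the pad-with-
foreground convention of the usual erosion routines.  A layer between
depths (a, b] is `{a < d <= b}` computed from a single transform, so any
depth grid partitions the mask *exactly* — the half-open boundary
assignment is the one convention that makes the partition identity hold
voxel-for-voxel.  Opening and closing use the same EDT erosion/dilation
adjoint pair and are therefore exactly idempotent; note that single voxels
lying at exactly the kernel radius can fall on either side of a digital
closing, a discretization effect, not a bug.

## Carpet projection and area weights

The radial band [r_min, r_max) of the aligned cylindrical cloud is binned
into a (θ × z) raster of mean intensities; empty bins are NaN and flagged
separately from zero intensity.  θ bins wrap; all bins are half-open.
Every in-band point lands in exactly one pixel and the per-pixel point
lists are stored CSR-style, so carpet regions map back to voxel index sets
losslessly.

The embryo surface is modelled as a radius graph R(θ, z).  Per bin, R is
estimated as the *outermost* point radius (the band has finite thickness;
the mean radius would systematically underestimate the surface), gaps along
z coming from sampling aliasing are linearly interpolated, and the map is
smoothed with a 3×3 mean (wrapping in θ).  The pixel area weight is the
first fundamental form of that surface,

    w = R·Δθ·Δz · sqrt(1 + (R_θ/R)² + R_z²) = R·Δθ·Δz / cos α,

with α the angle between the outward normal and the radial direction,
computed by central finite differences (circular in θ).  Bins with
cos α < 0.2 — the projection poles and steep furrows — are flagged
unreliable and excluded from area sums.  The floor is a package choice; at
the pole the cylindrical parameterization degenerates and no pixel weight
is meaningful.  When a measured region covers a pole, the flagged cap is
estimated as a spherical cap π(a² + h²) from the outermost usable ring
(base radius a, axial overhang h), and stray unflagged pixels beyond that
ring are excluded to avoid double counting.  On synthetic ellipsoids
(voxel-accurate masks, ~200³ voxels) the weighted full-surface area agrees
with the marching-cubes mesh area to about 1%, and spherical-cap regions
with 2πRh to better than 1% — comfortably inside the 5%/3% bands the tests
assert.

## Morphometrics

Cell objects are 26-connected components of a binary stack (or the labels
of a label stack).  Wall gaps up to 20 px are sealed by closing the
component with a ball of radius 10 px (pixels, not µm — the gap criterion
of the original filling routine is a pixel count) before interior filling;
components outside 200–10 000 voxels inclusive are dropped as artifacts.
Whether the bounds are inclusive is not biologically meaningful; inclusive
is the documented choice.

Height along a unit normal is the extent of voxel-center projections plus
the voxel box's support along that normal — algebraically identical to
projecting all eight corners of every voxel.  The footprint is the union of
voxel boxes projected onto the plane orthogonal to the normal, rasterized
at the smallest voxel pitch.  Circularity is 4πA/P² with the perimeter from
Moore boundary tracing using the Vossepoel–Smeulders calibrated step
weights (0.948 per axis step, 1.340 per diagonal).  Raw 1/√2 chain lengths
overestimate smooth digital contours by 5–10%, which would push a perfect
disc's circularity down to ~0.84; the calibrated weights bring a rasterized
disc to within a few percent of 1.  Tiny footprints (a few pixels) remain
outside the estimator's calibration range.

The two-class cell split (large/flat extraembryonic vs small/round
ectodermal) is 2-means on standardized (footprint area, height) with
deterministic initialization from the most separated pair of points; the
cluster with larger mean area is labeled extraembryonic.  Degenerate inputs
(identical cells, a single cluster) leave all cells unassigned with a
warning rather than fabricating a split.

## Kinematics

Region areas are sums of carpet pixel weights; overlapping a flagged pole
pixel is an error unless the caller opts into cap extrapolation.

Phase detection fits a continuous two-breakpoint piecewise-linear model by
exhaustive least squares over all breakpoint pairs on the sample grid (each
segment ≥ 3 samples; the basis is {1, t, (t−b₁)₊, (t−b₂)₊}, so each
candidate is a 4-parameter linear fit).  A pause is reported only if the
three-segment fit improves the residual by ≥ 10% over a single line *and*
the middle slope magnitude is below a fifth of the smaller phase slope —
the first rule alone would accept spurious breakpoints on noisy single
lines, the second encodes what "pause" means.  An exactly constant series
is reported as a pause spanning the whole series.  Under the study
conditions the tests reproduce (slopes 500 and 800 µm²/min, 50-min pause,
5-min sampling, area noise 2% of the series mean), both breakpoints are
recovered within one frame in ≥ 90% of runs.

Closure is measured on ventral-view window masks as axis-aligned extents
(AP extent = "height", transverse = "width"); rates are ordinary
least-squares slopes over the frames with a nonempty window, sign-flipped
so shrinkage is positive; closure time is the first empty frame.

## Synthetic data

The generators define the conditions all recovery tests run under.

*Embryo volumes.*  An ellipsoid (AP semi-axis longest) with a bright shell
between the outer surface and an inner ellipsoid offset by the shell
thickness — this offset construction makes the analytic shell-volume oracle
exact.  The surface texture is a nearest-seed partition: seeds are a
Fibonacci lattice scaled to the ellipsoid at one seed per membrane-cell
area (default cell scale 6 µm); shell voxels whose two nearest seeds are
within 0.6 µm of equidistant are "membrane" and get 1.5× shell intensity.
Defaults (shell 200, interior 40, background 10, noise σ 5) are free
parameters chosen to look like a membrane-label recording; real intensity
statistics are not reproduced, so tests exercising segmentation robustness
speak to contrast ratios of this order, not to arbitrary recordings.  The
returned marching-cubes mesh of the implicit surface is the area oracle.

*Spreading series.*  A cap grows from the dorsal pole; its geodesic radius
(edge-graph Dijkstra on the mesh) is solved by bisection per frame so the
realized mesh area follows the piecewise-linear schedule to mesh
resolution.  When the uncovered complement drops below 12% of the total
surface (and closure rates are set), the open region switches to a ventral
elliptical window whose height and width shrink linearly at the prescribed
rates, sized at hand-off to match the open area and to reach zero
simultaneously; from then on the realized area (recorded per frame in the
truth table) follows the window, not the schedule.  Ventral-view 2D window
masks (0.5 µm/px) are emitted directly for closure analysis.

*Coupled motion.*  Substrate velocity is a stationary AR(1) (lag-1
coefficient 0.5, marginal SD 0.24 µm/frame ≈ 1 px/frame), mimicking slow
tissue oscillations; the cell velocity is ρ·v_s + √(1−ρ²)·(independent
AR(1)) + white noise, so the signed series have correlation ρ before noise.
Both channels are band-limited periodic random textures (feature scale
8 px) advected by Fourier phase shifts — subpixel-exact and wraparound-safe.
Frames are 20 s apart (ten samples per 200-s analysis window).  Note the
downstream analysis correlates *magnitudes* of the AP component, which
compresses weak correlations (|ρ| = 0.1 maps to a near-zero magnitude
correlation) and cannot distinguish anti- from positively-correlated
motion; the pipeline inherits this property of the method rather than
correcting it.

## Coupling analysis

Lucas-Kanade flow solves the windowed normal equations per pixel (15-px
window, Sobel gradients averaged over both frames — the symmetrization
removes most of the forward/backward bias — with three warp-and-refine
iterations); pixels whose structure-tensor smaller eigenvalue is below
1e-4·max(I)² are invalid.  On rendered translations the median error is
< 0.01 px and forward/backward antisymmetry < 0.01 px, against 0.2/0.1-px
acceptance bands.

ROI velocity series take the per-frame mean of |AP flow component| over the
valid ROI pixels — a 3-px band around the outline for the cell channel, the
filled area for the substrate channel (the band width is a package default;
the original description leaves it open).  The cross-correlation of the two
series is computed in every sliding 200-s window (stride one frame), each
window mean-removed and normalized by the full-window energies (so the
zero-lag value is the window's Pearson r); the functions are averaged
across windows and the summary coefficient is the zero-lag value (a
max-over-lag reduction is available via `reduction="peak"`; which reduction
the original analysis used is not documented, zero-lag is the conservative
default).  Per-window mean removal doubles as detrending of slow drift.

Negative controls re-pair each cell with a substrate that is not its own
(seeded derangement).  Group comparison reports Hampel flags (median ±
3 scaled-MAD; flagged, never auto-removed), a Pearson χ² goodness-of-fit of
the fitted normal on equiprobable bins (df = bins − 3) as the normality
check, and the two-sided unpaired t-test.

## Problem sizes and limitations

The test-suite and acceptance-script problem sizes — three ~200³-voxel
embryos for the geometry oracle, 50 noisy schedules, 12 cells per coupling
group at 96² px × 31 frames — were chosen so every statistical acceptance
band is comfortably resolved on a single CPU.  Known limitations: the
carpet parameterization is not geodesic (pole caps are estimated, not
measured); the magnitude-based coupling coefficient is blind to the sign of
co-motion; phase detection assumes exactly one pause; the generators model
neither optics (PSF, attenuation, anisotropic blur) nor cell-shape
heterogeneity, so recovery results certify the algorithms on their stated
conditions, not performance on arbitrary microscope data.
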