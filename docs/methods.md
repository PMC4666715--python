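# Methods

This note documents the models, estimators and numerical choices behind
`creasemap`, what the synthetic phantom does and does not emulate, and the
known limits of each stage.

## The synthetic meristem phantom

The phantom is an analytic implicit surface: the smooth union of a spherical
dome (radius `dome_radius`, default 30 μm — a typical Arabidopsis vegetative
meristem) and one sphere per lateral primordium, placed by azimuth and arc
offset from the apex and protruding by `bump_amplitude` beyond the dome.
Successive primordia default to golden-angle (137.5°) divergence with
increasing amplitude, like a spiral phyllotactic series.

The union uses a compactly supported C² cubic smooth-min,

    smin(a, b) = min(a, b) − (w/6)·max(0, 1 − |a−b|/w)³ ,

applied pairwise dome-then-bumps.  Outside the band `|a−b| < w` this is the
exact union; inside, the crease is rounded at scale `w` (`blend_width`,
default 3 μm, so creases are cell-scale rather than razor edges).  Because
the blend is C², the Gaussian curvature of the zero set is well defined
everywhere, and because it has compact support, widening `w` rounds the
crease **without** moving the organ's footprint or amplitude.  That is
exactly the handle the delayed-folding (katanin-mutant-like) variant uses:
`folding_delay_factor` multiplies `w`, giving shallower boundary folds at
matched organ size.

Curvature ground truth comes in closed form from the gradient g and Hessian
H of the implicit field: `K = (g·adj(H)·g)/|g|⁴`.  On a bare dome this
reduces to `1/R²` to machine precision; an explicit-graph saddle
`z = (x²−y²)/(2a)` (test scene) gives `K(0) = −1/a²`.

L1 nuclei sit on a Fibonacci lattice of pitch `nucleus_spacing` (5 μm, one
per epidermal cell) at `nucleus_depth` = 4 μm below the surface; lattice
sites whose inward offsets converge across a crease to closer than ~a
nucleus diameter are dropped (nuclei are solid bodies).  Reporter intensity
follows the simplest monotone coupling law,

    I = baseline + β · max(0, −K(p_surface)) ,

with β in a.u.·μm² (`coupling_beta`, default 4×10⁴ so that boundary nuclei
are several-fold brighter than the 100 a.u. baseline, matching the contrast
of boundary-enriched reporters).  The real intensity–curvature law is
unknown; only its monotone decreasing direction is used in any test.
Rasterisation draws a Gaussian membrane shell (σ = `shell_thickness`/2) over
the implicit surface and Gaussian nuclear blobs (σ = `nucleus_radius`/2),
adds i.i.d. Gaussian noise (`noise_sigma`) to both channels, and clips at
zero.  Identical spec + seed gives bit-identical stacks.

What the phantom does **not** emulate: cell walls and cell-to-cell intensity
variation, Poisson photon statistics, depth-dependent attenuation,
anisotropic PSF, time-lapse drift/bleaching, real growth (geometry is
prescribed).  Consequently, passing tests show the *pipeline* is correct and
calibrated under its stated geometry and noise model — not that biological
variability is handled.

## Surface detection (level set)

Initialisation: the membrane channel is smoothed (Gaussian σ = 1 μm,
anisotropy-aware), thresholded (Otsu on the log-intensity histogram by
default; ties count as inside), reduced to its largest connected component
and hole-filled with the grid base treated as closed (a dome clipped by the
stack bottom still yields a solid interior).  The signed Euclidean distance
to the mask boundary seeds the implicit field (negative inside).

Evolution: the membrane stain is a bright *ridge*, not a step edge, so the
attraction term advects the surface along the normalised intensity gradient
of the smoothed membrane channel — a flow that vanishes exactly on the ridge
crest, where the surface therefore equilibrates without the one-blur-width
inward bias a balloon-force/edge-stopping formulation would leave.  A
mean-curvature smoothing term, modulated by an edge-stopping factor
`g = 1/(1+(|∇I|/λ)²)` (λ = 90th percentile of `|∇I|`), regularises the
surface against noise.  Time steps obey the CFL bounds of both terms.

Reinitialisation uses the relaxation PDE `φ_t = sign(φ₀)(1 − |∇φ|)` with
Godunov upwinding and a subcell fix (cells straddling the zero crossing are
pinned to `φ₀/|∇φ₀|`), run to the band width; the zero set moves by less
than half the smallest voxel spacing.  (A geometric rebuild via marching
cubes + nearest-point queries was rejected: KD-tree queries degrade badly on
the highly structured point clouds marching cubes produces.)

Convergence is judged on actual surface displacement: successive
signed-distance snapshots (one per reinitialisation cycle) are compared near
the zero set, and the run stops when mean displacement per iteration falls
below `convergence_tol` (10⁻³ μm).  On noisy data the surface keeps
jittering at a small amplitude and the iteration cap applies; the presets
for replicated runs cap at 80 iterations, which is several cycles past
equilibrium at those grid sizes.

Accuracy on the analytic shell: noise-free, every mesh vertex is within
~0.2 μm of the true sphere; at 10% shell-peak noise the 95th-percentile
deviation stays well under 1 voxel.

## Curvature estimation

The zero set is triangulated by marching cubes in physical coordinates
(anisotropic spacing honoured), the largest component kept, normals oriented
along +∇φ, and open-boundary or grid-border vertices flagged as mesh
extremities.  Per vertex, neighbours within `neighborhood_radius` (default
15 μm, geodesic along mesh edges — a Euclidean ball can jump across a deep
crease) are expressed in a tangent frame built from the area-weighted patch
normal, and a quadric `z = ax² + bxy + cy² + dx + ey + f` is fitted by
weighted least squares, giving `K = (4ac − b²)/(1 + d² + e²)²`.

The fit weights are Gaussian in distance with σ = radius/3.  The full 15 μm
support is kept (robustness to mesh irregularity) but the weighting damps
the quartic term a pure quadric cannot represent; unweighted 15 μm fits on a
25 μm sphere overestimate K by ~18%, weighted fits are within ~8%, and the
bias falls quickly with sphere radius (2% at R = 50 μm, <1% at R = 100 μm).
Vertices with fewer than `min_neighbors` usable neighbours or rank-deficient
fits get NaN and an extremity flag.  Oversized neighbourhoods are
deterministically subsampled to 150 points per fit.

Known limit: 15 μm neighbourhoods low-pass the curvature field, so
structures smaller than the neighbourhood (young organs, narrow creases) are
smoothed; the organ-outline automation therefore uses a finer radius, and
fine-scale K values near small bumps should not be over-interpreted.

## Signal projection and nuclei

The reporter channel is blurred with a physical-units Gaussian
(σ = `blur_radius`, default 10 μm — the "radius" parameter is interpreted as
σ; the value is configurable if an FWHM reading is preferred) and sampled
along the inward vertex normal over `projection_thickness` (10 μm) at steps
no larger than the smallest voxel spacing; the vertex gets the mean (default)
or max of the samples.  Projection with the mean statistic is exactly linear
in the image.

Nucleus detection: matched filter at σ = expected_radius/2, local maxima
above 10% of the global max, greedy suppression at one nucleus radius (so
plateau ties give one record), then per detection the brightest z-slice of
the in-disc mean is selected and the raw-channel intensity integrated in the
disc on that slice.  On phantom scenes at ≤10% noise, recall and precision
are ≥95%; nuclei closer than a diameter are physically unresolvable and the
generator does not create them.

Zone assignment: `central` = within 20 μm of the apex; with an ablation,
`near_ablation` = a 5–25 μm annulus from the ablation rim and
`control_side` = the opposite side of the meristem (top-view angle from the
apex > 90° from the ablation direction).  "k brightest per zone" (default
k = 10) resolves the manual pick-10-nuclei protocol; brightness ranking is
an assumption, recorded here because the manual selection rule is unknowable.

## Units of analysis and exclusions

Quantification follows two rules before any statistic: mesh-extremity units
are dropped (curvature is unreliable there), and organ interiors beyond the
analysed stage are dropped (`stage_cutoff`, default 0: the quantified region
is the dome plus its boundary creases, the region a boundary-reporter
analysis outlines).  On synthetic scenes organ labels come from the
generator; on real stacks they are user annotations.

Vertices a fraction of a micrometre apart are not independent observations:
the default unit is a 5 μm cell-proxy patch (vertices aggregated on a cubic
lattice; mean K, mean intensity, any-extremity flag).  This puts n at a few
hundred — the scale of per-cell quantification — so p-values refer to cells,
not to mesh resolution.  Per-vertex units remain available
(`patch_size=None`).

These two choices were validated on the negative control the design
prescribes: with a homogeneous reporter (`coupling_beta = 0`) the measured
correlation is centred on zero (|r| ≲ 0.05, p > 0.05 in the large majority
of seeds).  Without them, the projection geometry alone produces a spurious
correlation (convex organ tips focus the nuclear layer into the sampling
ray; creases pool signal from both flanks), which per-vertex n ≈ 10⁴ turns
into arbitrarily small p-values.

## Binned statistics

Equal-count bins (default 8) over K; per-bin mean intensity with Student CI
half-width `t₀.₉₇₅,ₙ₋₁·s/√n`; overall Pearson r, Spearman ρ and LS slope; a
bilateral two-sample t-test (Welch by default, pooled optional) between the
lowest- and highest-K bins — the single extreme-bin contrast avoids implicit
multiplicity, and no multiple-testing correction is applied anywhere.
Degenerate inputs: identical constant groups give t = 0, p = 1.

The monotone-trend check used in end-to-end tests allows each bin mean to
exceed its predecessor by at most the two bins' combined CI half-widths:
bins on the flat (K ≥ 0) part of the coupling law have equal expected means,
so a literal non-increase has essentially zero probability under noise.

Calibration (checked by simulation at every run of the acceptance script):
under an independent null the extreme-bin test rejects at 5% ± 2 and the
per-bin 95% CIs cover the true mean at 95% ± 2 over 2000 simulations.

## Section measures

A longitudinal section is a thin maximal projection: the stack is resampled
by trilinear interpolation on a plane grid (pixel = smallest voxel spacing)
and the per-pixel max is taken across the thickness (2 μm default, 5 μm
variant).  The boundary section plane contains the dome axis and the
primordium centre, oriented so the in-plane axis points from apex to organ.

The surface profile is the mesh∩plane intersection, chained by shared
segment endpoints (profiles are not graphs over the horizontal axis once the
organ flank steepens) and cropped at the bump tip — beyond the tip lies the
organ's *distal* crease, which would otherwise capture the curvature-extremum
crease picker; the folding angle refers to the meristem-organ (proximal)
boundary.

Folding angle: the crease is the concave-curvature maximum of the resampled,
lightly smoothed profile; straight lines are fitted (total least squares)
over 10 μm arms starting just outside the rounded tip, and the angle between
the arm directions is returned (180° = flat).  Profiles with no concave
point above 0.01 μm⁻¹ (radius > 100 μm) count as flat.  The measured angle
tracks the analytic-profile angle within ~5° at these grid sizes; at
near-flat boundaries (>177°) the quantity itself becomes ill-conditioned.

Expression area: largest above-threshold connected component within 15 μm of
the surface curve, in μm².  For punctate nuclear signal the section is first
smoothed (2 μm) so the expressing domain is contiguous.  Wild-type vs
delayed-series comparisons use one Otsu threshold per matched pair (pooled
band pixels) and boundary-restricted scenes (near-zero baseline), mirroring
two genotypes imaged with identical settings.

Organ top-view area: shoelace formula on a closed outline; the analytic
reference is the planimetric projection of the bump cap outside the dome
(what an outline drawn from above encloses).  The automatic outline floods
the curvature mesh from the organ tip until the negative-K crease ring
blocks it.  On desk-scale organs (7–10 μm radius) the crease band is a large
fraction of the organ radius, so outline placement within the band moves the
area by tens of percent; automatic and analytic areas agree to within ~50%
and should be treated as matched labels, not precision measurements.

## Replicated-run study sizes

Replicated checks run on a two-primordium 24 μm dome at 1.5 μm isotropic
voxels with the level-set iteration cap at 80 (the surface equilibrates in
3–4 reinitialisation cycles at this size): 100 seeds for coupled-scene
recovery, 50 for the homogeneous control, 2000 simulations for test-size and
CI-coverage calibration, 20 matched boundary pairs for the delayed-folding
contrast.  One pipeline pass at this size takes on the order of a second.

## Determinism

All randomness flows from explicit integer seeds (`numpy` Generator);
identical config + seed reproduces stacks, meshes, tables and reports
byte-for-byte.
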