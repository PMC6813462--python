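# Methods

## Track model and units

A track is one cell's ordered centroid samples $(t_i, x_i, y_i, z_i)$ with
time in seconds from acquisition start and coordinates in micrometres, in a
right-handed frame with $z$ increasing with imaging depth. Speeds are
reported in μm/min throughout (the field's convention); the s→min
conversion is centralized in one place. Tracks require at least two samples
with strictly increasing times; a missing frame simply yields a longer
interval — no gap interpolation is performed, because metric definitions
(duration-weighted arrest index, per-interval speeds) handle irregular
sampling directly.

Inclusion filters mirror common practice for intravital two-photon data:
≥ 12 time points **and** ≥ 180 s duration per track, and ≥ 20 visible cells
per imaging field. The point-count and duration rules are enforced
conjunctively and are independently configurable, because at 35–40 s frame
intervals the two phrasings of the classic "3-minute" rule disagree (12
points span ~7 min); the conservative intersection avoids silently choosing
one reading.

## Motility metrics

Per-interval speed is the centroid displacement over the interval divided by
its duration. Track velocity is the unweighted mean of these speeds. The
arrest index is the duration-weighted fraction of intervals at ≤ 2 μm/min —
identical to the per-time-point proportion when sampling is regular, robust
when it is not. Because "arrested" can be read per-track or per-population,
the pipeline reports both the cohort mean arrest index and the fraction of
tracks whose mean velocity falls below the threshold, labeled separately.
The meandering index is net displacement over path length, defined as 0 for
a zero-length path. Arrest episodes are maximal runs of consecutive
sub-threshold intervals; no smoothing is applied to instantaneous speeds.

Displacement (and MSD) curves evaluate $|p(\tau)-p(0)|$ on a regular τ grid
with linear interpolation between frames; tracks shorter than τ drop out of
that grid point rather than being extrapolated, so the per-point n is
non-increasing. The √time diagnostic regresses mean displacement on
$\sqrt\tau$: linear through the origin for a random walk, convex for
directed motion.

## Perivascular classification

Vessels are encoded as cylindrical segments (polyline centerline + radius).
Point-to-surface distance is the minimum over segments of the
point-to-polyline distance minus the radius, floored at 0 inside the lumen.
Classification is hierarchical: stationary (mean velocity ≤ 2 μm/min,
regardless of position), else perivascular motile if the track spends at
least `near_fraction` (default 0.8) of its duration-weighted time within
`near_distance` (default 10 μm, about one cell diameter) of a vessel
surface, else non-perivascular motile. No published quantitative definition
of "close to the vessel" exists, so both thresholds are explicit parameters
echoed into every output row rather than baked-in constants. Cells between
endothelium and basement membrane cannot be distinguished from fully
extravasated perivascular cells by distance alone; a single perivascular
class is used. Population fractions are averaged per field, with SEM across
fields (matching how imaging studies report n fields, not n cells).

## Synthetic cohorts

The generator is a discrete-time, two-state persistent random walk at the
acquisition frame interval (default 37.5 s, the midpoint of the 35–40 s
range; default volume 100 × 120 × 70 μm; default 49 points ≈ 30 min).
Each frame the cell:

1. switches state by a Markov chain (motile→arrested with `p_stop`,
   arrested→motile with `p_go`; initial state drawn from the stationary law,
   arrested fraction `p_stop/(p_stop+p_go)`);
2. draws a speed from a state-specific normal truncated at 0 (exact
   rejection sampling, so the truncated-normal mean is the recoverable
   target); defaults 6 ± 2 μm/min motile, 0 arrested — a fast-effector
   regime consistent with reported interstitial T-cell speeds;
3. turns by a von Mises–Fisher draw about its previous direction with
   concentration κ (κ = 0 exactly isotropic, sampled via the closed-form
   inverse CDF on S²), then mixes the result with ±`drift_axis` at weight
   `drift_bias`. The drift sign is fixed per track and sign-symmetric across
   the cohort: it models bidirectional channeling along the rostro-caudal
   axis, not advection toward a chemotactic source. `drift_bias`=1 with
   κ→∞ degenerates exactly to ballistic motion.

Dedicated modes: `ballistic` (straight constant-speed runs),
`brownian` (no switching; vectorized when fully isotropic),
`vessel_following` (each new position radially pulled back to within
`shell_um`, default 5 μm, of the nearest vessel surface), and `swarming`
(per-frame harmonic pull of strength `swarm_strength`, default 0.2, toward
the starting point — the pull strength is a free parameter of the emulation,
not a biological claim). Initial positions are uniform in the field volume;
tracks are not confined afterwards, mimicking cells leaving the imaged
volume. All randomness flows from one cohort seed through per-track
`SeedSequence` substreams, so cohorts are bit-reproducible and single tracks
can be regenerated in isolation.

What the generator does **not** emulate: localization noise, z-anisotropy of
detection, track fragmentation/identity switches, cell–cell interactions,
and real-data heterogeneity of per-cell parameters. Passing tests therefore
demonstrate correctness of the *analysis* under known ground truth, not that
real cohorts satisfy the generator's assumptions.

The mask generator builds spheres with radial Gaussian bumps
(surface radius $r(\theta) = R + h\,e^{-\theta^2/2\sigma^2}$, bump width
σ = 0.35 rad, pairwise separation ≥ 4σ enforced by rejection), giving
morphometry fixtures with protrusion counts known by construction. The
standard test fixture uses R = 5 μm, h = 2.5 μm (five voxels at 0.5 μm —
clearly resolved); the negative control uses h = 0.4 μm (sub-voxel).

## Morphometry

Volume is the foreground voxel count × voxel volume. The surface is the
0.5-level marching-cubes triangulation of the zero-padded occupancy grid
after a σ = 1 voxel Gaussian pre-smoothing — contouring the raw binary grid
produces a staircase surface that overestimates sphere area by ~8%, while
the smoothed contour is within ~2% of the analytic value; masks too small to
survive smoothing fall back to the raw grid. Meshes are welded, oriented
outward, and required to be watertight (Euler characteristic 2 for genus-0
cells).

Per-vertex mean curvature uses the cotangent-Laplacian estimator
($\mathbf K_i = \sum_j(\cot\alpha_{ij}+\cot\beta_{ij})(x_j-x_i)/2A_i$,
$H_i = \pm|\mathbf K_i|/2$ signed against the outward normal, convex
positive) followed by five rounds of one-ring averaging to suppress lattice
noise. Protrusions are connected patches of vertices whose curvature exceeds
**both** the mesh's 0.9 curvature quantile **and** 1.5× its median
curvature; a patch counts if the summed area of faces touching it reaches
`min_patch_area` (default: a spherical cap of height half a mesh edge on the
area-equivalent sphere, ≈ 8 μm² on the standard fixture). The rationale for
the two-part threshold: a pure quantile always flags the top decile of any
surface, so a featureless sphere would yield spurious patches wherever
voxelization noise concentrates; the absolute floor makes "plain sphere → 0"
structural. The patch-area default sits between measured lattice-noise
patches (≤ 6 μm²) and true bump patches (≥ 10 μm²); a full-voxel cap height
(~16 μm²) would sit *inside* the bump range, because quantile capping limits
a k-protrusion cell's per-patch area to roughly $(1-q)A_{total}/k$.

Commercial "surface mode" vertex/curvature pipelines are proprietary, so
absolute vertex counts from this module are not comparable to vendor
outputs; only relative contrasts (more/fewer vertices, larger/smaller
volume between conditions) are meaningful.

## Statistics

Mann–Whitney U uses the exact null distribution for tie-free samples with
max(n) ≤ 10 (validated against full enumeration of all rank assignments up
to n₁+n₂ = 12) and the tie-corrected, continuity-corrected normal
approximation otherwise; its type-I error at α = 0.05 is confirmed nominal
over 5000 null simulations. Kruskal–Wallis (≥ 3 groups, tie-corrected H,
χ² p) returns H = 0, p = 1 for identical groups. The t-test is
pooled-variance by default with Welch as a flag. Slope comparison fits each
group by OLS and tests the group × abscissa interaction of the pooled
4-parameter regression (two-sided t); numerically perfect fits are resolved
by the coefficient itself (identical lines → p = 1, distinct exact lines →
p = 0) instead of a 0/0 standard error. The Grubbs screen is the two-sided
single-outlier variant with critical value
$\frac{n-1}{\sqrt n}\sqrt{t^2/(n-2+t^2)}$, $t$ the upper $\alpha/2n$
Student-t quantile at n−2 df. All p-values are raw; no multiplicity
correction is applied or implied.

"Chemotactic-index" style plots are handled by the same slope-comparison
machinery applied to a directionality ratio; the package does not define a
separate index.

## Pipeline

`analyze_tracks` composes filter → metrics → classification → population
fractions → displacement/MSD curves → pairwise Mann–Whitney comparisons of
velocity, meandering and arrest between groups, embedding the full config
snapshot, software version and seed in the report so every number is
recomputable. `run_blockade_contrast` aligns two cohorts (e.g. before/after
an adhesion-blocking antibody) and reports per-metric deltas with tests, the
non-motile fraction shift, and the displacement-slope comparison — purely
observational deltas, no causal language. Field metadata defaults to
counting tracked cells per field when no explicit field table is given.
Stage counts are conserved and logged (tracks in = kept + rejected).

## Problem sizes and numerical choices

Monte-Carlo validations use 2000 tracks for random-walk scaling (MSD within
3× the sample SE; √τ regression R² ≥ 0.98), 200–500 tracks for parameter
recovery (arrest index 0.5 ± 0.05 under symmetric switching; mixture mean
speed within 3× SE of the truncated-normal target), 100 seeded replicates of
500-track cohorts for slope-test power, and 5000 pairs for the type-I error
check — sizes at which the checked tolerances are comfortably above Monte-
Carlo noise. Degenerate inputs are defined explicitly: zero path length →
meandering 0; empty vessel geometry → infinite distance, motile tracks
classified non-perivascular with vessel metrics flagged unavailable; zero
variance → Grubbs undefined, no outlier; empty fields excluded from
population summaries with a warning.

## Known limitations

Manual-tracking error models, track linking, and image segmentation are out
of scope: the package consumes centroid tables. The perivascular thresholds
are conventions, not measurements. Mouse-level clustering is not modeled
(cells are pooled within condition, as is common in this literature);
mixed-effects extensions would be straightforward on top of the per-track
metrics table. The morphometry module's absolute counts depend on mesh
resolution and are only meaningful as within-pipeline contrasts.
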