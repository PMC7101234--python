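# Methods

This note documents the models, conventions, and numerical choices behind
`spindlemorph`, in the order the pipeline runs.

## Geometry model and units

All reconstruction geometry is stored in nanometers; every reported scalar
statistic is in micrometers (conversion factor exactly 1000) or degrees.
Coordinates are 0-based and right-handed, with no implicit axis flipping.
Chromosome surfaces are closed (watertight) triangle meshes; voxel-mask
inputs are converted to meshes at load time by marching-cubes isosurface
extraction at level 0.5, so downstream code sees a single surface
representation. A chromosome's "center" is the area-weighted surface
centroid, not a bounding-box center. The spindle axis is the unit vector
between the two pole centroids, each pole centroid being the mean of that
pole's centriole centroids.

Two geometry kernels are implemented directly on raw triangle arrays:
point-to-triangle closest distance (vectorized region classification of the
point/triangle projection) and Möller–Trumbore ray-triangle intersection.
Both are exercised against dense-sampling oracles in the test suite.

## Kinetochore-microtubule classification

A microtubule is a KMT when the minimum distance over its polyline
**points** (not interpolated segment positions) to a chromosome surface is
at most the kinetochore-zone thickness (default 150 nm, the measured
extent of the ribosome-free zone around the holocentric chromosomes).
Candidates are tested against the X chromosome first; only microtubules
with no X association are assigned to the nearest autosome within the
threshold. This X-priority ordering reflects that anaphase microtubules
pass between the autosomes before reaching the univalent X. Ties between
equidistant autosomes break toward the lower chromosome id and are logged;
each microtubule gets exactly one association.

The putative plus end of a KMT is the endpoint with the smaller surface
distance to its chromosome (for non-KMTs: the endpoint farther from the
nearest centriole), matching spindle polarity. The association is *end-on*
when a 150 nm extrapolation beyond the plus end intersects the chromosome
mesh, else *lateral*. The extrapolation direction is the chord spanning the
final 100 nm of arc length rather than the literal last digitization
segment, which suppresses tracing noise; the last-segment behavior remains
selectable (`direction_mode="segment"`).

## Tomogram morphometry

* **Arc length** is the polyline chord sum; **tortuosity** is arc length
  over end-to-end distance and is undefined (error) for closed paths.
* **Chromosome stretch**: orthogonal planes are placed along the spindle
  axis at 10 nm spacing; the mesh cross-sectional area in each plane forms
  a profile to which a sum of five Gaussian components is fit by nonlinear
  least squares with multi-start initialization (centers spread over the
  profile support, three deterministic starts, bounded parameters). The
  FWHM is read numerically from the fitted curve on a 1 nm grid (half of
  the fitted maximum, outermost crossings). If no start converges to a
  residual below 20 % of the profile maximum, the raw-profile FWHM is
  reported and flagged (`fit_ok=False`). The five-component family is
  flexible enough that the fitted FWHM matches analytic values on
  spherical (√2·r) and Gaussian (2√(2 ln 2)·σ) profiles to well under 2 %.
* **Polymer box ratio**: two cubes of side 1 µm (configurable), faces
  perpendicular to the spindle axis, abut the X chromosome's axial bounding
  planes (offset configurable, default 0) and are laterally centered on the
  X centroid. Polymer length is the exact sum of polyline segments clipped
  to each cube (slab clipping). Side 1 faces pole 1. The lateral
  orientation of the cube cross-section is seeded from the model's own
  geometry (the lowest-id autosome centroid) so the statistic is invariant
  under rigid motions of the whole reconstruction.
* **Staging distances**: the autosome-autosome distance is the mean over
  homolog pairs of the centroid distance between pair members when
  `pair_id` annotations exist (preferred); otherwise the two groups are
  split by the sign of the axial coordinate relative to the spindle
  midpoint and the group-centroid distance is used. The mother–daughter
  centriole split is averaged over poles.

## Live-imaging dynamics

Spindle poles are segmented per frame by thresholding the tubulin channel
at 50 % of the per-frame maximum after median-background subtraction (Otsu
optional); the two largest components are the poles, with intensity-weighted
centroids and voxel-count volumes. The relative threshold makes every
dynamics output invariant to global intensity scaling. Pole identity is
propagated between frames by minimal displacement.

Chromatin components are assigned by axial position: the extreme components
are the segregating autosome groups and the dimmest interior component is
the lagging X. When the groups are merged into one component (typical at
metaphase, where the separation is below the axial PSF), the group
separation falls back to a three-Gaussian shared-width fit of the axial
chromatin intensity profile — outer components are the groups, the middle
one is the X sitting between them. This mirrors the kymograph-peak
measurement used on real data and resolves separations well below the
component-splitting limit, at the cost of a residual ±0.1–0.2 µm bias for
heavily overlapped metaphase configurations.

**Anaphase onset** is this package's own operational definition: the last
baseline frame before the first frame whose value departs from the
metaphase baseline by more than three baseline standard deviations with the
departure persisting over the next two frames. Implementation details that
matter: candidates are scanned as explicit breakpoints so the baseline
statistics never include post-onset frames; baseline location/spread use
median and MAD (again contamination-proof); the SD estimate is floored by
a robust whole-series noise scale (lower quartile of absolute
frame-to-frame changes) to guard against pathologically small
short-baseline estimates; and a 2 SD step-back recovers a first anaphase
frame that just missed the 3 SD test. The detector is direction-agnostic,
so the same code aligns rising separation curves and shrinking
pole-to-autosome curves, and (via `detect_onset_curve`) signed X-position
traces. Returning the *breakpoint* rather than the first exceeding frame
removes a systematic one-frame delay that would otherwise bias every
first-minute rate fit low by ~10 %.

**Initial rates** are least-squares slopes over the first 60 s after onset
(inclusive of the onset frame), reported in µm/min with a standard error;
initial and final lengths are the metaphase-baseline and trailing-plateau
means, and the elongation duration is the time from onset until the curve
settles within noise of the final plateau. Pole-to-autosome rates are fit
on curves aligned to the onset detected from the accompanying
autosome-separation curve — the standard alignment signal — because the
per-frame P-A change (~0.13 µm at 20 s sampling) is marginal against
0.05 µm localization noise.

**Axis resampling** interpolates each frame trilinearly onto an isotropic
0.1 µm grid aligned with the pole-pole axis, spanning the pole separation
plus an extrapolation at each end; defaults (radius 0.9 µm, extrapolation
1 µm) serve kymographs and (3 µm, 2 µm) display projections. The
**kymograph** is, per axial plane and frame, the fluorescence sum weighted
by exp(−r²/2σ²) in radial distance from the axis. The kernel width is a
free parameter; the default σ = 0.3 µm (a third of the cylinder radius) is
wide enough to suppress voxel noise and narrow enough not to blur the pole
peaks, whose positions are refined to sub-voxel accuracy by parabolic
interpolation. All frames are centered on the spindle midpoint.

The **X shape coefficient** z/((x+y)/2) is measured on the thresholded
(half-maximum) mask extents of the X in the axis-aligned resampled volume,
so z is exactly the spindle-axis extent. The **box intensity ratio** sums
tubulin fluorescence in two 1 µm³ cubes abutting the X's axial extent;
box 1 is the side the X resolves toward. Photobleaching correction is a
simple ratio normalization of per-frame foreground means against the first
frame (foreground fixed by Otsu on frame 0); it exactly flattens a global
exponential decay and intentionally does nothing more sophisticated.

## Anaphase decomposition

The A/B partition uses plateau means: ΔAA (total separation gain),
anaphase B = ΔPP, anaphase A = 2 × mean ΔPA. The two fractions are
reported as measured and not forced to sum to one — with measured
endpoints they typically sum to ~0.98 of ΔAA.

The three-factor anaphase-A budget is closed-form arithmetic on measured
inputs: stretch release = factor × (FWHM_metaphase − FWHM_anaphase) with
factor 2 by default (the relaxation acts on both chromosome flanks;
factor 1 gives the raw FWHM drop and is one config switch away);
centrosome reshaping = difference of range midpoints of the
plus-end-to-centriole distance; angle opening = L·(cos α₁ − cos α₂) at
constant microtubule length L. The `explained_fraction` divides their sum
by the total chromosome-to-pole shortening.

## Synthetic data generator

The generator defines the conditions every recovery test runs under.

**Geometry.** Five paired autosome ellipsoids (semi-axes 250 × 250 ×
280 nm, the axial one scaled by a stretch factor) sit on a 1 µm ring
around the central X ellipsoid (300 × 300 × 350 nm); homologs sit at
±A-A/2 along the axis. Stage presets set pole-pole separation,
autosome-autosome distance, centriole split and X offset to the scale of
staged reconstructions (metaphase 3.41/0.94/0.21 µm through late anaphase
7.04/5.44/1.11 µm). Microtubules are grown with designed labels: end-on
KMTs terminate 40–120 nm from their chromosome aimed at the surface
(autosomal lengths 0.65 ± 0.10 µm; X-associated ones span 78–92 % of the
way to their pole, emulating the continuous pole-X tethers that lengthen
with pole separation); lateral KMTs run tangentially with their closest
vertex 40–120 nm from the surface; non-KMTs stay outside every kinetochore
zone by a 30+ nm margin. Each placement is validated against the actual
classification rules with clearance margins and retried (bounded), so the
generator's labels are exact by construction — recovery tests read truth
only from the generator. Default counts mirror a full metaphase
reconstruction (2406 microtubules, 912 KMTs); tests use 24–150
microtubules and (where speed matters) icosphere subdivision 2 instead of
the default 3.

**Kinetics.** Distances follow the saturating exponential
D(t) = D₀ + (D_f − D₀)(1 − e^(−t/τ)) — the simplest form consistent with a
measured initial rate, fixed endpoints, and continuously decelerating
separation. Defaults are the measured meiosis-I values: P-P 4.1→8.0 µm at
1.29 µm/min, A-A 0.9→6.5 µm at 2.07 µm/min, P-A 1.6→0.8 µm at
−0.39 µm/min; the movie renderer derives P-A from P-P and A-A, making the
partition identity exact by construction. Because an "initial rate (first
minute)" is operationally the slope of a linear fit over the first minute
of a decelerating curve, the default calibration (`first_minute`) chooses
τ so the noiseless first-minute secant equals the quoted rate;
`instantaneous` instead makes the t→0⁺ derivative equal it (the two differ
by ~15 % in the recovered first-minute slope). The lagging X stays at the
midzone until an onset drawn from N(4.9, 1.5²) min, then moves toward a
random side at a speed drawn from a normal with mean 2.2 and SD
0.9 µm/min truncated at 0.1 (consistent with the observed 0.7–4.9 µm/min
range); the kinematic trace is uncapped, while the renderer caps the
drawn position at the target autosome group for visual realism.
`draw_x_speeds(..., antithetic=True)` draws speeds in quantile pairs
(u, 1−u): each draw keeps the exact marginal distribution while the
ensemble mean has strongly reduced Monte-Carlo variance, which is what an
ensemble-mean measurement wants.

**Rendering.** Poles are 3D Gaussian spots; chromatin bodies are Gaussian
blobs whose half-max extents match the body axes with the PSF (σ = 0.35 µm
axial, 0.15 µm lateral) added in quadrature; an optional β-tubulin line
adds a spindle-long ridge (normalized so its peak stays a fixed fraction
of pole brightness, with a configurable gain on the X's target side).
Voxels default to 0.3 × 0.1 × 0.1 µm, frames every 20 s, peak signal 200
photons with Poisson shot noise plus Gaussian read noise (SD 2). The PSF
and noise levels are package choices set to give realistic segmentation
SNR; all are configurable. The spindle axis is deliberately tilted in the
volume so axis resampling is genuinely exercised.

**What the generator does not emulate**: microtubule mechanics and
force balance, optical aberrations and depth-dependent PSFs, sample drift,
photobleaching beyond a multiplicative decay, chromatin substructure, and
segmentation confounders such as neighboring cells. Passing recovery tests
therefore demonstrate correctness of the measurement pipeline under the
stated imaging model, not robustness to every property of real data.

## Numerical conventions and degenerate inputs

Geometry round-trips are bitwise: JSON floats via repr, CSV via `%.17g`
on write and round-trip float parsing on read. Coincident polyline
endpoints make tortuosity an error (closed path); coincident poles make
the axis an error. Frames with fewer than two pole components are flagged,
not guessed. Missing distance measurements are NaN and excluded from fits;
an empty second polymer box yields an infinite ratio rather than a crash.
Ellipsoid voxelizations for shape-coefficient measurements use odd grid
sizes so the body center falls on a voxel center, making the measurement
deterministic.

## Known limitations

* The merged-group axial fit biases metaphase A-A by up to ~0.2 µm when
  the group separation is far below the axial PSF; anaphase measurements
  are unaffected.
* The end-on/lateral rule depends on the plus-end definition; for KMTs
  whose two endpoints are nearly equidistant from the chromosome the
  assignment can flip under digitization noise (not observed with the
  generator's margins).
* Chromosome-stretch FWHM assumes a single connected cross-section
  profile; touching chromosomes should be segmented apart upstream.
* `stage_metrics` group splitting assumes the two autosome sets straddle
  the spindle midpoint, which holds from metaphase onward but not for
  pathological monopolar configurations.
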