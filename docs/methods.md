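# Methods

This note documents the models, algorithms, defaults and design choices in
`stamps3d`, and what the synthetic-data tests do and do not demonstrate about
real measurements.

## Measurement principle

A multi-layer insole with a plastically deformable (plasticine) mid-layer of
nominal thickness 5 mm accumulates permanent deformation over a period of
gait. Its top surface carries a high-contrast stochastic speckle pattern.
Stereo images taken before and after walking are correlated subset-by-subset;
triangulating the matched points in both states gives a 3D displacement field
on the surface, from which surface strain is computed. The measurement is
cumulative by construction: it trades temporal resolution for full-field
spatial coverage, and the strain it reports reflects the combined action of
pressure and shear at the foot–insole interface.

## Synthetic ground truth

**Speckle.** Dots are placed uniformly at random with overlap permitted;
diameters are uniform in `d₀·[1−v, 1+v]`. The dot count `n` is solved from the
expected coverage after overlap, `1 − (1 − ā/A)ⁿ = ρ`, where `ā` is the mean
dot area — so the *measured* covered-area fraction matches the target density
(±5 pp at 512², converging with image size). Dot edges get ~1 px analytic
anti-aliasing; coverage is measured as mean dot opacity. Defaults follow the
commercial-generator convention of 65 % density, 0.8 mm dots, 75 % variation.
Polarity (dark-on-light) is configurable. Placement is deliberately *not*
Poisson-disc: the statistical spec, not a particular proprietary placement, is
what matters for matchability.

**Insole geometry.** The outline is a smooth foot-shaped closed polygon
(wider forefoot than heel, medial arch concavity), mirrored for left feet.
Contoured surfaces add a medial arch bulge plus a heel-cup/lateral rim, built
on a coarse grid (distance-to-edge from the outline) and interpolated with a
bicubic spline, normalised so the maximum height equals `arch_height_mm`
(default study value 12 mm). The anatomical convention is: x anterior,
y medial (right foot), z up; left feet mirror y.

**Plastic deformation.** Deformation is a sum of Gaussian bumps: each carries
a radial in-plane stretch (engineering strain `ε` at the centre) and a normal
indentation (`depth` mm at the centre), `u = ε·g·(x−c) − depth·g·ẑ` with
`g = exp(−r²/2σ²)`. The true strain table is obtained by differentiating the
analytic displacement (central differences at 10⁻³ mm, exact to ~10⁻⁸). The
functional form is a modelling choice — a plasticine layer deforms smoothly
and locally under bony prominences, but no specific constitutive behaviour is
claimed. `make_deformation` accepts a seed reserved for optional stochastic
roughness; the default field is deterministic.

**Cameras and rendering.** Cameras are ideal pinholes (zero distortion) in a
verged pair: 15° total vergence at 400 mm standoff, focal length scaled so a
~270 mm insole spans ~78 % of the image width. Rendering is inverse: each
(supersampled 2×2) pixel ray is intersected with the deformed surface by a
joint fixed-point iteration on the height field and the material-coordinate
inversion `x = X − u(x)`, then the speckle texture is sampled at the
*material* point with bicubic interpolation. Non-insole pixels are uniform
background. The renderer is validated by phase correlation: a rigid in-plane
translation reproduces the predicted image shift to < 0.05 px (the oracle uses
plain, unwhitened cross-correlation on an interior crop; spectral whitening is
biased by resampling distortion near Nyquist). Lens blur, shadows, specularity
and sensor noise are *not* modelled — accuracy numbers on synthetic renders
are therefore upper bounds on real-image performance.

**Study simulation.** `simulate_study` draws regional peak records
`truth × (1 + ε)`, `ε ~ N(0, noise_cv)`, independent across repeats, for the
5 participants × 3 conditions (low-stiffness contoured, high-stiffness
contoured, flat) × 3 repeats design; `global` rows hold the across-region
maximum. Because a zero-noise study must reproduce its effect profile exactly
through the metrics stage, the between-participant heterogeneity factor
defaults to 0 and is opt-in. Paired peak-pressure records for the flat
condition are generated either through a Gaussian copula on the realised mean
strains — with `ρ_z = 2·sin(π·ρ_s/6)` so the *Spearman* target is imposed in
expectation — mapped through a lognormal scale (median 180 kPa, log-sd 0.6,
spanning the plausible 50–600 kPa range), or through a deterministic monotone
link. Pressure repeat noise defaults to CV 5 %, matching the repeatability of
in-shoe pressure systems. The default effect profile is a set of round
numbers with the qualitative contoured-vs-flat pattern (heel/lateral loading
up under an arch profile, medial forefoot down); it is a synthetic scenario,
not data.

## Stereo DIC

Matching minimises the zero-normalised SSD (equivalently maximises ZNCC),
which is exactly invariant to affine intensity changes. Defaults: 21 px
subsets, 10 px grid step, 30 px integer search radius, ZNCC threshold 0.8,
inverse-compositional Gauss–Newton with a first-order (affine) subset shape
function, bicubic (cubic B-spline) interpolation, convergence at an update
norm (subset-scaled) of 10⁻⁴, 50 iterations max. All are configuration, not
claims: real studies tune them to their optics. Convergence is checked
*before* applying a sub-tolerance update, so a self-match returns displacement
exactly zero. Measured subpixel bias on synthetic speckle is ~0.002 px mean
absolute (bound asserted: 0.05 px).

The grid driver matches three pairs — stereo at the reference state, temporal
(reference camera), stereo at the deformed state (initialised from the
reference disparity) — propagating initial guesses breadth-first from the
highest-ZNCC full-search seed (ties broken by grid index, so runs are
deterministic), with a full-search fallback when a propagated guess fails.
Nodes failing quality are flagged invalid, carried as NaN and never
interpolated. Triangulation is linear DLT (SVD), reporting the mean two-view
reprojection error; zero baselines and near-parallel rays raise. If fewer
than 50 % of ROI nodes validate, the run fails with a per-node quality map.
The ROI is auto-detected from local image contrast (speckle has high local
standard deviation, background none) unless a polygon is supplied.

## Surface strain

Per node, neighbours within `2.5 ×` the median node spacing (Gaussian
distance weighting, σ = radius/2) enter a least-squares fit of the 3×2 tangent
deformation gradient mapping reference tangent coordinates to 3D deformed
offsets. `E = (FᵀF − I)/2` is then expressed on tangent axes aligned with the
anatomical AP/ML directions. Because the fit uses full 3D deformed offsets,
rigid motions are strain-free by construction (verified to < 0.2 % for a 10°
rotation). The directional measures are the signed parts of the normal
strains (S_ANT = AP tension, S_POST = AP compression, etc.); this reading of
"anterior/posterior strain" is a declared interpretation. S_Z is the local
normal displacement over the nominal layer thickness, positive for
indentation — surface DIC cannot observe through-thickness strain directly,
so this is the natural surrogate. S_MAG combines the in-plane tensor norm
(doubled shear term) with S_Z in quadrature, in percent, unclipped (values
above 100 % are legitimate); the definition lives in one function
(`smag_percent`) so alternatives can be swapped.

The anatomical frame comes from the principal axis of the outline vertices;
anterior is the wider end (feet are widest at the forefoot), overridable by a
heel hint; near-circular outlines (extent ratio < 1.2) are refused without a
hint. Strain brackets for absolute maps are half-open `[lo, hi)` at
0/2.5/5/7.5/10 %, the last open above.

## Plantar mask

The 11-region template partitions the unit foot domain by AP bands (heel
0–0.27, midfoot 0.27–0.55, MTH 0.55–0.73, toes 0.73–1.0) with ML splits
(midfoot 45 % medial; MTH columns 30/20/17.5/17.5/15 % from medial; toes
35/20/45 %). The commercial multimask's exact percentages are proprietary;
these defaults are declared and fully configurable, and the tests are written
against the configuration rather than the numbers. Registration scales AP and
ML extents independently (feet vary in aspect ratio — a deliberate extension
of plain similarity), rotates into the anatomical frame, and mirrors for left
feet implicitly through the medially-positive ML axis. ML scaling is global
(one width for the whole foot), not per-band. Registered region polygons are
clipped to the outline, so their areas close the outline area exactly; 3D
nodes are assigned by AP–ML projection (the mask is 2D even on contoured
surfaces), with boundary points resolved by the declared region precedence
order.

## Metrics and statistics

"Peak" is the single maximum valid node per region (a percentile option
exists, default off); empty regions are missing, never zero. Cohort summaries
are two-stage medians — median across a participant's repeats, then the
median and 25th–75th IQR of per-participant medians — with single-stage
pooling available. The repeatability CV uses the sample (n−1) standard
deviation, material at n = 3 repeats; note the estimator is biased low at
n = 3 (median of the sample CV ≈ 0.83 σ/μ for Gaussian noise), which is why a
23 % generator noise reads back as ~19 % median CV. That is a property of the
CV-at-3-repeats estimator, not of the generator.

The Friedman statistic uses mid-ranks and the tie-corrected χ² form with k−1
degrees of freedom, evaluated with the χ² asymptotics even at n = 5 blocks
(Monte-Carlo calibrated: empirical size ~0.04 at α = 0.05, inside
[0.02, 0.08]; the discreteness at small n makes the test slightly
conservative). An exact permutation option enumerates all within-block
orderings for verification at small designs. Block values are per-participant
medians across repeats (consistent with the median-based summaries);
all-repeat blocks are available. Post-hoc pairs use the exact Wilcoxon
signed-rank at n ≤ 25 (a sign-test alternative is provided), Bonferroni
factor = number of pairs, adjusted p capped at 1. Degenerate inputs (all-zero
differences, constant Shapiro–Wilk cells) are reported with explicit notes
rather than errors; constant cells count as non-normal by convention.
Strain–pressure correlation is Spearman with mid-rank ties over participant ×
region cells (repeats averaged by mean), restricted to the flat condition —
in-shoe pressure insoles cannot follow compound curvature — with bands weak
< 0.4, moderate 0.4–0.69, strong ≥ 0.7 and significance at p < 0.05; cohort
rho pools all cells, per-participant rhos are reported alongside.

## Problem sizes and numerical choices

Tests, examples and the acceptance script run the imaging chain at a reduced
desk scale chosen as a deliberate design point: 640 × 400 renders (512 × 320
for the smallest pipeline checks) instead of the full 1920 × 1200 capture
size, with speckle dots enlarged to 2.2 mm so they stay > 3 px at the coarser
image scale, grid steps of 10–14 px, and Monte-Carlo sizes of 150–1000
replicates depending on the estimator. All quantitative assertions are in
physical units (mm, %), which the reduced scale keeps meaningful; the
full-resolution geometry is exercised directly where it matters (triangulation
noise propagation). Deterministic seeds flow from a single integer through
`numpy.random.default_rng`; no global RNG state is used anywhere. File writes
are atomic (temp + rename); CSVs use a fixed `%.9g` float format so identical
runs are byte-identical.

## Known limitations

* The renderer's idealisations (no lens distortion, blur, noise or lighting
  variation) mean synthetic accuracy figures bound, but do not predict,
  real-camera performance; calibration error is likewise absent.
* Strain is surface strain on the reference tangent plane; no constitutive
  model of the plasticine, no stress estimation, and no decomposition of the
  cumulative deformation into its pressure vs shear origins.
* The mask is geometric: no landmark- or pressure-driven placement, and no
  per-participant anatomical customisation beyond outline registration.
* The study simulator's noise is multiplicative Gaussian and independent
  across repeats; real gait variability is structured (fatigue, footwear
  interaction) and typically larger in low-strain regions.
* Second-order subset shape functions, incremental time-series DIC and
  camera calibration from target images are out of scope.
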