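# Methods

This note documents the models, numerical choices and known limitations of
`arraytomo`.  It is written for a maintainer or reviewer deciding whether a
given measurement can be trusted, and what a passing test suite does and
does not demonstrate.

## Imaging model and coordinate conventions

A stack is one 3D array per channel, shaped `(sections, rows, cols)`.
Coordinates are 0-based voxel indices; physical positions sit at voxel
centres with `x = col·dx`, `y = row·dy`, `z = section·dz`.  Defaults are
`dx = dy = 0.1 µm` and `dz = 0.07 µm` (the physical thickness of an
ultrathin array tomography section).  The axial thickness is not stated
alongside a lateral pixel size in typical acquisitions of this kind, so
0.1 µm/px is an explicit assumption recorded in the run configuration, not
a measured value.  All volumes, distances and densities downstream are in
µm³, µm and µm⁻³.

## Synthetic scenes

The generator reproduces the *statistical* structure the analyses assume,
not the biology of neurites:

* **Presynapses** are a homogeneous Poisson process (`pre_density`,
  default 0.5 µm⁻³ — a realistic cortical synapse density at the lower
  end).  Puncta are axis-aligned ellipsoids (semi-axes 0.3 µm lateral,
  0.2 µm axial) rendered at constant amplitude 200 counts.
* **Paired postsynapses**: a fraction `paired_fraction` (default 0.8) of
  presynapses receives a partner at an isotropic centroid offset drawn
  uniformly from 0.1–0.45 µm, i.e. always inside the 0.5 µm pairing
  criterion.
* **Tau assignment**: presynapses carry tau with probability `p_pre`;
  paired postsynapses with probability `q1` when the partner carries tau
  and `q0` otherwise (orphan posts use `q0`).  The implied enrichment
  ratio `q1 / (p_pre·q1 + (1−p_pre)·q0)` is stored with the truth, so the
  estimator can be checked against a closed form.
* **Tau puncta** (semi-axes 0.7× the host) are placed fully inside their
  host, so ground-truth colocalization at the ≥ 25 % criterion is
  unambiguous: 0.7³ ≈ 34 % of the host volume, comfortably above the
  threshold.  A partial mode instead programs a stated overlap fraction
  (solved by bisection on a deterministic sample grid of the tau
  ellipsoid) to probe the threshold boundary.
* **Astrocyte arbors** are direction-correlated random-walk filaments
  (Gaussian steps smoothed along the path) dilated to a target volume
  fraction; the final dilation shell is subsampled to land on the target.
  Walks are seeded through the puncta chosen for engulfment, so engulfed
  centroids end up inside the mask without moving any synapse.
* **Optics**: per-section rigid jitter (uniform in ±`jitter_translation_max`
  px and ±`jitter_rotation_max`°; the first section anchors the frame and
  gets identity), Gaussian PSF blur, Poisson photon noise followed by
  additive Gaussian read noise, bright single-section speckles
  (secondary-antibody precipitate), and optional quantization.

**Identifiability by construction.** Paired posts are placed such that the
true partner is also the post's *nearest* presynapse (rejection sampling),
and orphan posts are placed with no presynapse within the pairing radius.
Without this, nearest-neighbour pairing at 0.5 µm mispairs ≈ 6 % of posts
at density 0.5 µm⁻³ (the chance a rival presynapse falls closer than the
true partner), which attenuates the estimated enrichment ratio by ~3 %
relative — an artifact of the scene construction, not of the estimator
under test.  The generator therefore guarantees that the ground-truth
pairing graph is exactly what a correct pairing implementation should
recover; robustness to *imaging* confounds is probed separately through
the optics model.

**Seeding.** One scene seed drives six named substreams (placement, flags,
astrocytes, jitter, noise, speckles), so changing the noise model never
moves geometry, and regeneration is bit-identical.

**What passing tests do not show.** Scenes have no neurite morphology, no
spatially varying background, no section folds/tears, no chromatic offsets
between channels, and puncta of a single size and brightness.  Recovery
statistics (object F1 ≈ 0.93, enrichment within Monte-Carlo error) are
therefore upper bounds on what identical settings would achieve on tissue.

## Registration

Pairwise transforms between consecutive sections are estimated on a
reference channel (the presynaptic channel by default, as the most
ubiquitous marker) and composed into the frame of section 0; drift over
≤ 30 sections is accepted rather than bundle-adjusted.  Translation comes
from phase cross-correlation with 100× Fourier upsampling; rotation from a
coarse grid over ±5° (step 0.5°) followed by bounded scalar minimization
of the phase-correlation residual (tolerance 0.005°).  Both images are
low-pass filtered (σ = 1.5 px) first: consecutive physical sections image
different slices of the same structures, and suppressing slice-specific
high frequencies reduces rotation bias about threefold in our
measurements.  Interpolation is bilinear (nearest-neighbour mode available
where exactness matters).  Voxels warped in from outside the frame are
marked invalid and excluded from all analyzed volumes.  A section whose
estimate fails (e.g. featureless image) receives the identity and a
logged flag.  Measured recovery on noise-free scenes with ±3 px / ±1°
jitter: ≤ 0.32 px and ≤ 0.1° per section after composition.

## Segmentation

Per section: median background subtraction (disk radius 15 px; the
background can be estimated on a 4× coarsened grid and re-interpolated —
it is smooth by construction, and this cuts the filter cost 16-fold), then
the auto-local threshold `value > local_mean(31 px) + k·SD + ε`, with
`k = 2.5` and SD per window (Niblack family).  Two numerical points:

* `ε` is a scale-relative guard (10⁻⁹ × image max) against the running-sum
  rounding residue of the uniform filter, which otherwise marks
  exactly-zero background downstream of bright pixels as "above its local
  mean".
* `k = 2.5` keeps the background false-positive rate ≈ 0.6 %.  Much lower
  offsets leave enough background positives to percolate through the
  26-connected lattice into large multi-section noise objects.  An
  alternative `"global"` SD mode (robust per-section noise SD via MAD) and
  an optional matched-filter pre-smoothing (`smooth_sigma`, for
  acquisitions at SNR ≲ 5) are provided; both default off.

3D objects are 26-connected components of the stacked masks.  Components
spanning fewer than 2 physical sections are removed (single-section
secondary-antibody speckle — with 70 nm sections a real punctum always
spans several), as are components under 10 voxels.  Touching puncta are
split by marker watershed on the smoothed anisotropic distance transform;
seed peaks closer than 0.3 µm within one component are merged greedily
(deepest first), so an isolated convex punctum never splits, and distinct
components are never merged.  Objects above 2 µm³ (configurable; no
standard value exists) are flagged somatic and excluded from neuropil
metrics while remaining in the table.

## Colocalization and pairing

Object-level colocalization divides the intersection with the partner
*mask union* by the object's own volume, so how the partner channel was
split into objects cannot change the result; the flag is inclusive at the
25 % boundary.  Voxel-level colocalization ("% of staining") uses the same
masks with an optional somatic exclusion.  An empty denominator is
reported as missing with a warning, never as zero.

Pairing is post-centric nearest-neighbour within 0.5 µm (inclusive) in
physical coordinates; a presynapse may serve several postsynapses.  The
enrichment baseline is all paired posts (a tau-negative-pre baseline is
computed as a secondary column but never reported as the headline ratio).
Undefined ratios (no tau-positive pres, zero baseline) carry a reason
string and propagate as missing values.

One caveat the synthetic scenes make visible: with pair offsets below the
punctum diameter, a postsynaptic object can overlap the *partner's* tau
punctum in the shared tau channel, inflating both the conditional and the
baseline probability; the two biases largely cancel in the ratio (measured
≈ 3 % low at the default conditions).

## FRET

Coefficients are single global least-squares slopes through the origin
over above-threshold control pixels (d: I_DA on I_DD in donor-only; a:
I_DA on I_AA in acceptor-only) — per-pixel ratios are unstable at low
intensity.  The corrected stack `Fc = I_DA − d·I_DD − a·I_AA` keeps
negative values; clipping is for display only.  "Any FRET signal" is
`Fc > 0` within the donor∩acceptor mask; a configurable noise-floor bound
exists because pure positivity is noise-sensitive (symmetric noise at zero
true signal yields ≈ 50 % positive).  Per-case means are tested against 0
with a classical one-sample t-test, Bonferroni-multiplied across
comparisons and capped at 1.

## Aggregation and transforms

Stacks within a case are technical replicates; case means (arithmetic,
ignoring missing values) are the biological unit.  The Tukey ladder
searches λ ∈ [−10, 10] in steps of 0.025 (x^λ for λ > 0, log x at 0,
−x^λ for λ < 0 — monotone on positive input for every rung) and keeps the
λ maximizing Shapiro–Wilk W; the criterion choice is a convention and is
recorded in output metadata.  Zeros are offset by half the smallest
positive value (offset recorded).  λ is weakly identified when the
coefficient of variation is small — every rung is then near-affine and
the W surface is flat.  Mixed-model fitting is deliberately out of scope:
the package exports tidy tables with their formula strings so any
standard mixed-model tool can fit them reproducibly.

## Problem sizes used in the checks

Test scenes are 20–30 µm fields over 10–18 sections; the enrichment
recovery uses 100 seeded 50 × 50 × 1.4 µm scenes (≈ 1750 presynapses each)
estimated at truth level, and `scripts/acceptance.py` uses 60 scenes per
enrichment arm plus one fully rendered 30 µm scene for registration,
segmentation and speckle checks.  These sizes give Monte-Carlo standard
errors a few times smaller than the effects being checked.
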