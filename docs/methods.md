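# Methods

This note documents the models, parameters and design choices behind
`strokedti`: what each stage computes, what the synthetic study does and
does not emulate, and where numerical conventions had to be fixed.

## Atlas space and hemisphere convention

All data live on one 3-D grid (default 48³ voxels of 0.2 mm, RAS-like
axes: x = left→right, y = anterior→posterior, z = ventral→dorsal) with a
flat Allen-style region ontology (11 analysis regions — cc, SSp-un/ul/ll,
SSs, MOp, MOs, ACA, DORsm, DORpm, STRd — under container nodes). Both
hemispheres carry identical label ids; hemispheres are separated by a
single midsagittal index plane, voxels on which belong to *neither*
hemisphere. This exclusion rule avoids double counting in
ipsi ∪ contra decompositions and is asserted as a set-partition property
in the tests. Registration of real MRI into this space is out of scope;
inputs are assumed atlas-aligned (NIfTI-1 via nibabel).

## Lesion mapping

- **Volume**: true-voxel count × voxel volume (mm³).
- **Affected regions / incidence**: a region counts as affected when at
  least `min_voxels` (default 1 — no minimum overlap is imposed) of its
  ipsilesional voxels fall inside the mask; incidence is the fraction of
  subjects affected, per region and day.
- **Percent infarct**: 100·|mask ∩ region|/|region| on the ipsilesional
  region mask.
- **Consolidation slope**: (p₇ − p₁)/6 in percentage points per day; the
  denominator is elapsed days, fixing a unit the original description
  leaves open.
- **Ward clustering** of lesion profiles (per-region percent-infarct plus
  total volume) uses the standard Lance–Williams minimum-variance update
  on squared Euclidean distances, with merge heights reported unsquared
  (scipy convention: two singletons merge at their Euclidean distance).
  The inter-cluster distance for a k-cluster cut is the height of the
  merge that would fuse k clusters into k−1; the intra-cluster distance
  is the largest merge height inside any retained cluster. Statistical
  GUIs print agglomeration schedules on other scales, so these distances
  are comparable within this package only.

## Diffusion metrics

Tensors are stored as the six unique components (xx, xy, xz, yy, yz, zz)
in mm²/s. Eigenvalues come from a vectorized symmetric eigensolver;
FA/MD/AD/RD use the standard closed forms, and FA is clipped to [0, 1].
Voxels with an eigenvalue below −10⁻¹² are flagged degenerate but their
metrics are still returned. Regional values are voxel *means* (the
choice between mean and median was open; mean matches the linear
averaging used everywhere else). Hemispheric asymmetry is
(ipsi − contra)/contra × 100 %; the "integrated density" of a region on
T2 is its size-normalized summed intensity — i.e. the mean — and is
reported as the ipsi/contra ratio of means (a raw integrated sum was
rejected because region sizes differ between hemispheres only by the
midline rule, but the normalized form is the stated definition).

## Tractography

A deterministic tensor-line (FACT-style) tracker: from each seed the
streamline is integrated in both directions with a fixed Euler step
(default 0.25 × the smallest voxel dimension), following the principal
eigenvector of the *nearest voxel's* tensor, sign-aligned with the
previous step. Termination: FA < 0.15, turning angle > 60° per step,
leaving the brain mask, or 2000 steps. Defaults are conventional DTI
choices and all sit in `TrackingParams`. Nearest-voxel tensor lookup
(no interpolation) keeps the contract simple and fully deterministic but
makes thin, strongly curved bundles leak streamlines — visible in the
synthetic study as sub-proportional densities for the thinnest tubes;
the analytic-phantom tests bound the trajectory error at < 2 steps
Hausdorff on a circular field.

Seeding places `seeds_per_voxel` (default 3) uniformly jittered points
in every source-region voxel, deterministically per `rng_seed`. Fiber
density is the number of streamlines with ≥ 1 point in the target
region divided by the number of seeds; a streamline contributes at most
once per (source, target) pair regardless of re-entries, and raw counts
are kept alongside. No directionality is claimed — DTI cannot orient a
pathway — so ordered (source, target) pairs are a seeding convention
only. Tracer validation computes the sample covariance and Pearson ρ
(Spearman optional, since a rank coefficient is arguably the more robust
choice) between the per-target DTI densities and a viral
projection-density reference, plus both descending rank orders.

## Statistics

- Holm–Šídák step-down for families of two-tailed Welch t tests
  (pooled-variance optional): sorted raw p₍ᵢ₎ →
  1 − (1 − p₍ᵢ₎)^(m−i+1), enforced monotone. Both-samples-constant
  comparisons return p = 1 by convention.
- The group × time analysis is a subject-random-intercept two-factor
  model. With complete balanced data it is computed exactly as a
  split-plot RM-ANOVA (closed-form sums of squares; group tested against
  subjects-within-groups, day and interaction against the within-subject
  residual) — this path is fast enough for the 500-replicate null
  calibration, and is verified against pingouin's implementation.
  With missing cells it falls back to a statsmodels MixedLM fit (ML) with
  Wald term tests; the exact covariance structure used by the original
  GUI software is unknowable, so random-intercept is the documented
  choice. Per-day pairwise contrasts are emitted only when the
  interaction or a main effect is significant, Bonferroni-adjusted over
  the emitted family.
- Kruskal–Wallis uses the tie-corrected H; Dunn's post hoc z tests run
  only on a significant omnibus and are Holm-adjusted by default (the
  adjustment family is configurable because GUI defaults differ).
- Mann–Whitney is exact for small tie-free samples, normal-approximated
  with tie correction otherwise; identical pooled samples return p = 1.
- Correlations report r, R² and a two-sided p — t-transform for n ≥ 8,
  exact/randomized pairing permutations below that.
- Slope comparison fits per-group OLS and tests slope equality through
  the day × group interaction in the pooled model.

## The synthetic study

The generator plants, at the voxel level, the statistical structure the
analysis is meant to detect. Defaults are the study conditions; every
effect is individually zeroable, and `EffectSizes.null()` (which also
collapses the two lesion-protocol geometries into one) makes the three
groups exchangeable so that downstream tests attain nominal type-I
error.

**Design**: n = 5 small-stroke, 4 large-stroke, 4 sham subjects; days
−3 (baseline), 1, 3, 7, 14, 21, 28; all strokes right-hemispheric (the
analysis accepts a per-subject side).

**Lesions** are axis-aligned ellipsoids clipped to the dorsal
ipsilesional quadrant (cortex plus callosal depth). In-plane semi-axes
shrink by √(shrinkage factor) between days 1 and 7 — volume folds of 4.3
(small) and 1.7 (large) — continuing mildly afterwards; a separately
calibrated day-28 "histology" mask plays the role of the final
glial-scar segmentation. Per-subject size is lognormal (σ = 0.15) and
shared across days, so cohort volume *ratios* concentrate; centers
jitter by 0.5 voxels. Ellipsoid centers and axes were calibrated once,
at design time, so that default cohorts reproduce the target cohort
statistics: day-1 separation ≈ 1.8, day-28 separation ≈ 2.7, and group
mean MOp coverage ≈ 77 %/2.5 % (day 7) and ≈ 71 %/22 % (day 28).

**Tensors**: a mildly anisotropic background (FA ≈ 0.1, below the
tracking threshold), lesion voxels near-isotropic with elevated MD, and
prolate-tensor tubes (FA ≈ 0.75) painted along smooth spline centerlines
for three pathway systems — five ipsilesional DORsm→cortex branches with
graded radii (SSp-ul > SSp-ll > MOp > MOs > SSs, matching the tracer
reference's rank order), a midline-crossing contralesional DORsm →
ipsilesional SSp-ul bundle, and transcallosal MOp→MOp/MOs bundles — plus
an unmodulated mirror of the thalamocortical system in the healthy
hemisphere so control region metrics are left-right symmetric. Group ×
day schedules scale tube radius (hence seedable cross-section, hence
fiber density) and anisotropy: the large group's ipsilesional system
degrades progressively to 0.55× radius at day 28 while its crossing
bundle recovers from 0.55× to 1.0×; the small group's crossing bundle
declines persistently. Ipsilesional DORsm RD is additionally raised
(peak +20 %, with a small early dip) in the large group. The acute
lesion is painted *before* the tubes: pathway density is governed by the
planted schedules rather than by the edema footprint, which keeps the
acute/chronic contrast of the density analysis interpretable; the
trade-off is that thin tube transections through the lesion retain high
FA, so the "lesion is near-isotropic" contract holds for the bulk of
lesion voxels, not every voxel.

**T2** is uniform tissue intensity (100) plus an acute lesion
hyperintensity (+60, decaying with a 7-day constant) and a late
ipsilesional DORsm hypointensity in the large group (−10 % by day 28,
emulating iron accumulation), with Gaussian noise (σ = 2).

**Behavior** (hindlimb drops, paw drags %, foot faults %) follows
baseline + coupling × severity × exp(−(day − 1)/τ): severity is the
day-1 lesion volume weighted up by day-1 MOp involvement (weight 2 per
unit coverage — lesions that hit motor cortex hurt disproportionately),
with subjects expressing the group-typical severity plus a damped
(0.25×) individual deviation; τ = 12 d (small) vs. 7.5 d (large), so the
large group's worse acute deficit converges to the small group's level
by day 28. Noise is truncated normal within each measure's valid range.
The damping reflects that behavioral scores integrate damage imperfectly;
it preserves a positive deficit–volume correlation while keeping
within-group spread realistic for n of 4–5.

**What the generator does not emulate**: registration error, partial
volume and susceptibility artifacts, probabilistic fiber geometry,
crossing-fiber voxels, biophysical ischemia or MR signal formation, and
histology image processing. Passing tests therefore demonstrate that the
*analysis* recovers planted effects of realistic size under clean
atlas-space data — not that it would survive real-world registration or
acquisition noise.

## Problem sizes in the test suite

The suite runs on one CPU: exhaustive voxel-loop oracles use random
volumes up to ~16³; analytic tracking phantoms use ≤ 32³ fields; cohort
parameter recovery and sign recovery average 20 generated studies;
statistical calibration uses 500 null and 200 planted-effect
replicates. These sizes were chosen so each oracle stays exact (or its
Monte-Carlo error well below the asserted margin) while the whole suite
completes in a few minutes.

## Known limitations

- Nearest-voxel tracking underestimates density for bundles thinner than
  ~1 voxel radius and can drop them entirely; density is therefore a
  relative measure, comparable across groups and days but not an
  absolute connection strength.
- Ward linkage heights are scale-dependent (units of the profile
  features); only their ordering and the inter/intra contrast are
  meaningful.
- The mixed-model path reports Wald tests, which are anticonservative
  for very small samples; the balanced split-plot path is exact under
  its assumptions and is preferred whenever the design is complete.
- The CLI's stage commands recompute shared prerequisites rather than
  sharing a daemon; caching is file-level and keyed only by output
  presence, so stale tables must be cleared with `overwrite`.
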