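# Methods

This note records the models, conventions and numerical choices behind
`vulquant`, and what the synthetic-data generator does and does not
emulate.

## Conventions

Arrays are ordered `(z, y, x)`; ventral is increasing `y`, anterior is
decreasing `x`, so the VPC row P3.p…P8.p has strictly increasing x.
Coordinates are 0-based voxel/pixel indices; all ranges are half-open.
Physical calibration (µm per voxel along z, y, x) travels with each stack
in a JSON sidecar next to the TIFF.

## Polarity measurement

The pipeline for one AC stack is: summed z-projection over the imaged
slab → seeded segmentation → median background subtraction outside the
mask → two-compartment mean ratios.

**Segmentation.** An Otsu threshold is computed in a square window
(default half-size 30 px, roughly three nucleus diameters) around the AC
nucleus centre, so other fluorescent cells in frame do not move the
threshold. The nucleus seed must exceed the Otsu value, which validates
detection; the final footprint threshold is then *relaxed* to
`background + 0.25 × (otsu − background)`, with background estimated as
the median of sub-Otsu window pixels. The rationale: a summed projection
of a convex cell falls off gradually at its rim (the projected chord
length goes to zero), and a strict Otsu cut through that graded rim
removes rim pixels asymmetrically between the brighter and dimmer halves
of a polarized cell, biasing the half-mean ratio toward 1 (about −10% at
a true ratio of 2 on the synthetic default geometry). With the relaxed
threshold the excluded rim is ~1% of the footprint and the residual bias
is below 0.5%. The mask is the 8-connected supra-threshold component
containing the seed, holes filled.

**Splitting.** Halves are mask pixels strictly on either side of the line
through the nucleus centroid perpendicular to the axis; pixels exactly on
the line belong to neither half (unbiased tie-break). A line through the
nucleus centre need not split the mask into equal areas, so both half
areas are reported and an imbalance above 25% is flagged for review.
`I_DV` is oriented ventral/dorsal; `I_AP` proximal/distal with the
proximal side chosen from the nearest-VPC geometry (the caller passes the
orientation, so the index stays > 1 for enrichment toward the VPC
regardless of whether the AC sits anterior or posterior of it).
Statistics are masked-only; background subtraction (median outside the
mask, clamped at zero, applied after projection) precedes the ratio, and
a regression test asserts the known artefact that an additive offset
inside the mask pulls the ratio toward 1.

Classification thresholds default to 1.1 for the ligand channel and 1.2
for the PIP2 membrane-marker channel (approximately the 10th percentile
of wild-type index distributions); comparisons are strict.

## Alignment and staging

Distances are centroid-to-centroid Euclidean distances in the projection
plane, in µm. `R = d(AC, target)/d(target, reference)` with the reference
the anterior neighbour (P5.p for target P6.p) when the AC x-coordinate is
at or anterior of the target's, the posterior neighbour otherwise; exact
ties resolve anterior and are logged. Categories use the strict
breakpoints `R > 0.09` (no longer fully aligned) and `R > 0.4`
(misaligned). Staging bins by gonad length are half-open lower-inclusive
— [30, 70) early/mid-L2, [70, 110) late-L2, [110, 150] early/mid-L3 —
resolving the touching printed ranges at 70 and 110 µm in favour of the
later stage; lengths outside [30, 150] µm are labelled out-of-range
rather than erroring.

## Biosensor quantification

Activity per VPC is the nuclear red/green (H2B / KTR) mean-intensity
ratio in a summed projection of the five central slices around the H2B
focus (even window sizes put the extra slice below focus; windows are
truncated at stack boundaries with a warning). The nucleus mask is
segmented from the red channel only — the green signal varies with
activity — and applied identically to both channels. P3.p is excluded
structurally because it adopts a VPC fate in only about half of animals.
Each animal's ratios are normalized to the mean of its own P4.p–P8.p
ratios, so normalized profiles average to exactly 1; the highest-in-P6.p
call requires a strict maximum, with ties counted as "not highest"
(conservative) and logged.

## Statistics

- `VI` is the plain mean of per-animal induced counts; counts are
  validated to multiples of 0.5 in [0, 6] (half-fates are standard in
  vulval scoring). Per-animal classification is strict against 3.
- Bootstrap: resamples of size n with replacement; SEM is the SD of the
  resample means; the 95% CI is percentile-based by default, with a
  normal-approximation (± 1.96·SEM) option; method, seed and resample
  count are carried in the result. Default 10,000 resamples.
- Fisher's exact test sums hypergeometric probabilities not exceeding the
  observed table's, with a `1 + 1e-7` relative factor absorbing
  floating-point ties; it matches an exact-rational enumeration oracle on
  randomized tables.
- Mann–Whitney U (U reported for the first sample, ties counted half) is
  exact by full permutation enumeration over mid-rank assignments when
  the combined sample size is ≤ 12, and uses the tie-corrected normal
  approximation with continuity correction above that (accurate to ~0.02
  at n = m = 7 against enumeration). The branch taken is determined by
  the sample sizes alone.
- t-tests (Welch and pooled-variance Student) delegate to scipy; the
  two-sided F-test places the larger variance in the numerator and
  doubles the upper tail, capped at 1.
- All tests are two-sided; no multiple-testing correction is applied —
  results are per-comparison, as is conventional for per-figure
  significance reporting in this field.

## The synthetic-data generator

**AC stacks.** The AC is an ellipsoid (default semi-axes 9 × 14 × 14
voxels in a 26 × 72 × 72 volume at 0.13 × 0.1 × 0.1 µm) of base intensity
200 photons over a background of 10, with Poisson noise on signal +
background followed by Gaussian read noise (SD 5). Polarization is a
two-compartment *step* in expected intensity, not a gradient, because the
measured quantity is a two-compartment mean ratio. Multiplicative
ventral/dorsal and posterior/anterior factors are solved on the
rasterized ellipsoid by fixed-point iteration so the noiseless
compartment-mean ratios equal the requested `rho_dv` and `rho_ap` to
machine precision; voxels exactly on a split plane carry factor 1 and
belong to neither compartment. Punctae are Gaussian blobs (default 10,
amplitude 100, σ 1.2 voxels) placed uniformly inside the ellipsoid by
rejection sampling and clipped to the mask; they contribute well under 1%
of total signal, so they perturb rather than dominate the polarity — the
true punctate/cortical partition of the real ligand distribution is not
quantitatively known, and the puncta load is a free parameter, not a
biological claim. The ground-truth record reports the compartment means
of the noiseless signal including punctae and excluding background,
which is exactly what a background-subtracted measurement estimates.

**Animal layouts.** VPCs are collinear along x with 77 px (10 µm at 0.13
µm/px) default spacing; the AC offset relative to P6.p is configurable
with optional uniform jitter. The true R is recorded per animal. The
attached AC stack is a zoomed crop around the AC in its own coordinate
frame — as in practice, where polarity is measured at higher
magnification than the annotation overview.

**Biosensor images.** Five soft-edged spherical nuclei at the focal
plane; red amplitude fixed at 150, green amplitude 150/activity, so the
noiseless nuclear red/green ratio equals the injected activity exactly
and independently of the mask, because both channels share the same
spatial profile. Background 4, Poisson noise, read noise SD 2; the red
and green noise streams are split deterministically from the animal seed.

**Cohorts.** Fate patterns (wild-type / hyperinduced / hypo-induced /
shifted) are drawn per animal from configured probabilities; induced
counts come from per-pattern distributions whose defaults put the
wild-type mass entirely on 3.0 and spread hyper-/hypo-induced mass over
counts above/below 3 in 0.5 steps, weighted toward mild phenotypes as is
typical of partial-penetrance mutants.

Every generator is a pure function of (parameters, seed): identical
inputs give bit-identical arrays.

**What the generator does not emulate.** No optics: no PSF, no
depth-dependent attenuation, no bleaching, no chromatic offset between
channels, and no deconvolution artefacts (deconvolution is treated as
optional external preprocessing, recorded in provenance). Cells are
ideal ellipsoids/balls; real ACs are irregular, and real nuclei can
overlap neighbouring signal. Consequently, passing tests demonstrate
that the measurement code is correct and unbiased on data matching its
geometric assumptions at realistic noise levels — not that segmentation
is robust to every real-world imaging pathology.

## Problem sizes

The validation suite measures 100 synthetic animals per polarity level
(`rho_dv` ∈ {1.0, 1.2, 1.5, 2.0}), 200 noisy biosensor replicates, and
2,000 null replicates at n = 30 vs 30 for the type-I-error calibration
of the two-sample tests; these sizes give binomial/median standard errors
comfortably inside the asserted bands while keeping the full suite under
a minute of compute.

## Known limitations

- The polarity split line through the nucleus centroid does not
  guarantee equal half areas; flagged animals (imbalance > 25%) should be
  reviewed rather than silently accepted.
- Whether the original semi-automated measurement subtracted background
  before or after projection, and before or after forming halves, is not
  derivable from its description; this pipeline subtracts after
  projection and uses masked-only statistics, and records both choices in
  provenance.
- Missing or fused VPCs abort a biosensor profile rather than imputing;
  cohorts with such animals must handle them upstream.
- `R` uses centroid-to-centroid distances; edge-to-edge distances would
  differ for large nuclei at small separations.
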