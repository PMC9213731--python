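# Methods

`adaptqa` implements the evaluation chain used to decide whether unedited
auto-propagated organ contours are good enough for online adaptive
replanning in pancreatic SBRT: geometric contour QA near the target,
DVH-based constraint evaluation of competing plans on the ground-truth
contours, and cohort statistics linking near-target contour error to
dose-constraint violations.  Because no patient imaging is distributed with
the package, the chain is exercised end-to-end on a synthetic
organ-deformation phantom whose statistical structure matches what the
analysis assumes.

## Voxel model and distances

All masks and dose grids live on one shared axis-aligned voxel lattice
(`GridGeometry`: shape, spacing in mm, origin at the center of voxel
(0,0,0)).  There is deliberately no resampling: objects on mismatched
geometries raise an error, mirroring a workflow in which all structures and
doses for a fraction are defined on that fraction's CT frame.

Distances are Euclidean distances between voxel centers with anisotropic
spacing honored, computed with exact Euclidean distance transforms
(`scipy.ndimage.distance_transform_edt`).  The signed distance of a
structure is negative inside (distance to the nearest outside voxel
center, negated).  Isotropic expansion by *r* keeps every voxel whose
unsigned distance is ≤ *r*; rings are differences of expansions and
therefore tile exactly (ring(0,d₁) ∪ ring(d₁,d₂) = ring(0,d₂), disjointly,
with the target interior always excluded).

The voxel-center convention matters at sub-voxel scales: the zero level of
the signed distance sits about half a voxel inside the continuum surface
of a voxelized solid.  All internal consistency checks (oracle tests,
ring identities) are exact under this convention; comparisons against
continuum closed forms (sphere volumes, isodose volumes) carry an
O(spacing/2) surface bias and are made on 0.5 mm grids where that bias is
at the percent level.

## Contour agreement metrics

The four agreement metrics follow the registration-QA recommendations
(TG-132 style) on voxel masks:

* **DC** — Dice coefficient, 2|A∩B|/(|A|+|B|) on voxel counts.  Two empty
  masks give 1.0 (with a warning); exactly one empty gives 0.0.
* **MSD** — symmetric mean surface distance.  Surface voxels are defined by
  6-connectivity (a true voxel with a face-adjacent false voxel; the grid
  boundary counts as outside).  Both directed means are combined weighted
  by surface-voxel count.
* **HD** — exact (100th percentile) symmetric Hausdorff distance.  No
  percentile trimming, since the quantity of interest is the worst-case
  surface separation.
* **VOL_DIFF** — auto minus manual volume in cc; positive means the
  auto-contour overestimates.

Surface metrics refuse empty inputs (the metric is undefined); the batch
comparison (`compare_structure_sets`) instead emits a flagged row when a
clipped pair is empty, so cohort tables never die on a distant organ.

Proximity measures: **MIN_DIST** is the minimum over OAR voxel centers of
the signed target distance (negative = deepest penetration into the
target); **OVLP** is the volume of the OAR inside the target expanded by
0.5 or 1 cm.  Clipped structures are the OAR intersected with the expanded
PTV; OAR voxels inside the PTV are retained, since they dominate the dose
impact.  Default clip ladder 30/10/5 mm; default ring partition 0–15 vs
15–30 mm with 0–10/10–30 and 0–20/20–30 available.

The combined GIO structure (stomach ∪ duodenum ∪ bowel) is a plain voxel
union; overlapping voxels count once.

## Dose model and DVH evaluation

Doses are absorbed dose per voxel in Gy with an attached prescription
(40 Gy in 5 fractions, prescribed to the 80% isodose line, so the maximum
dose is 50 Gy).  DVH quantities are voxel-count statistics with a closed
threshold bound (a voxel exactly at the threshold counts toward VxGy), and
the constraint comparator is strict (< limit passes, = limit violates);
both conventions are stated because cc-level near-maximum constraints are
sensitive at boundaries.  Coverage is the percentage of the target volume
receiving ≥ 95% of prescription (38 Gy).  Target Dmin is the literal
minimum over structure voxels, not a near-minimum percentile.

The default constraint set encodes the protocol: stomach, duodenum and
bowel each V35 Gy < 0.5 cc; optionally liver V20 Gy < 700 cc, kidneys
Dmean < 15 Gy and V15 Gy < 30%, cord Dmax < 27.5 Gy.  The phantom emits
only the three GI organs; the extra organs are supported in the constraint
format for real structure sets.

Every plan, however it was optimized, is evaluated on the designated
manual (ground-truth) contour set — the central design rule of the
analysis.

## The synthetic phantom

Per patient, a planning scene on a 56×56×48 grid at 2.5 mm (140×140×120
mm): a 10 mm-radius spherical GTV expanded by 5 mm to CTV and 2 mm more to
PTV; an ellipsoidal stomach a few mm from the PTV; a duodenal tube that
grazes or slightly overlaps the PTV mid-arc and sweeps outward toward its
ends (so the organ has mass both near the target and 15–30 mm away); and a
sinuous bowel tube passing below the target.  Organ placement gets ±3 mm
per-patient jitter so the cohort spans a range of target–organ proximities,
with the duodenum closest (median MIN_DIST near or below zero), as in
clinical pancreatic anatomy.

**Interfraction deformation.**  Each fraction's manual set is the planning
anatomy warped by a smooth random displacement field: white noise filtered
to a 25 mm correlation length (periodic filtering, which keeps the field
statistically stationary — edge-padded filtering would inflate variance at
the volume boundary and make the global normalization unrepresentative of
motion near the central target), zero-meaned, and rescaled so the 95th
percentile of voxel displacement magnitude is exactly the configured
amplitude (default 10 mm).  Masks are warped by linear pull-back
interpolation thresholded at 0.5, which keeps them binary and on-grid while
still responding to sub-voxel displacements (pure nearest-neighbor
resampling silently discards any shift below half a voxel, which at 2.5 mm
voxels would erase most realistic organ motion).  Targets are never
deformed, emulating fiducial-based target alignment; inverse-consistency
error of the pull-back is sub-voxel for these smooth fields and is
documented rather than corrected.

**Auto-contour error model.**  Each auto-contouring method is a profile:
a smaller smooth error field (default 95th-percentile amplitude 2–3 mm)
applied to the manual organs, plus an optional signed near-target bias that
pushes organ surfaces along the PTV distance gradient — negative pulls the
contour away from the PTV (near-target underestimation), positive pushes it
toward/into the PTV (overestimation).  The bias acts at full strength
within 3 mm of the PTV and tapers cosine-smoothly to zero over the next
4 mm, so it models exactly the failure mode of interest: contour error in
the high-dose region, invisible in whole-organ metrics.  A per-fraction
bias probability lets a cohort mix biased and unbiased fractions.  The two
default profiles emulate one slightly-underestimating and one
overestimating method (bias −2 mm and +3 mm).

**Dose surrogates.**  The planning dose is an analytic SBRT-like falloff
around the PTV: maximum dose deep inside (≤ −3 mm), a linear ramp to the
40 Gy prescription at the PTV surface, and 40·exp(−d/λ) outside with
λ = 25 mm, i.e. roughly 50% of prescription 15 mm from the target — a
representative gradient for tracked pancreatic SBRT.  (A much steeper λ
would place the 35 Gy isodose within a fraction of a voxel of the PTV, so
near-maximum violations could arise only from direct target overlap and
the near-target error mechanism the cohort analysis is designed to detect
would be structurally suppressed.)  The "optimizer" is a constraint-capping
surrogate for full inverse replanning: it clamps dose to 34 Gy on the
organs it is given (including organ voxels inside the PTV — coverage loss
emerges exactly where organs overlap the target) and never increases dose.
Because 34 < 35, replanning on the *true* contours satisfies every V35
constraint by construction; a real optimizer's occasional failures are
explicitly not modeled.  The non-adapted (NoAd) dose is the planning dose
(capped on the *planning* organs) carried unchanged onto the fraction,
emulating dose transfer rather than recalculation.

Under these defaults roughly a third of non-adapted fractions violate at
least one V35 constraint — the qualitative regime in which adaptation is
worth evaluating — while manual-contour replans are always compliant.
Every stochastic entry point takes an explicit integer seed; per-patient
and per-fraction generators are derived deterministically from it, and
cohort generation is byte-reproducible (manifests, CSV reports) given the
same configuration and seed.

## Cohort statistics

Plan parameters are summarized as median and interquartile range (Q1, Q3)
and compared pairwise per fraction with the two-sided Wilcoxon signed-rank
test; ring-wise VOL_DIFF of violators vs non-violators is compared with the
two-sided Mann–Whitney U test.  Both tests drop zero differences, use
midranks for ties, and are computed *exactly* for small samples by dynamic
programming over the null distribution of doubled midrank sums (all 2ⁿ
sign assignments for the signed-rank test up to n = 25; all C(n₁+n₂, n₁)
group assignments for Mann–Whitney up to a pooled size of 30); above those
sizes the scipy normal approximations are used.  Two-sided p-values are
min(1, 2·min(lower tail, upper tail)) with inclusive tails.  No
multiple-testing correction is applied; each comparison is reported at its
own p-value with α = 0.05.

A replan *improves* on NoAd when its V35 Gy is ≤ NoAd's for all three GI
organs, strictly lower in at least one whenever any NoAd V35 is positive
(an all-zero tie counts as improved).  A fraction is a *violator* for a
given (structure, method) when that method's replan, evaluated on the
manual contours, fails that structure's constraint.  Mann–Whitney groups
smaller than 3 are flagged insufficient rather than tested, so a cohort
with no violators is all-insufficient, not an error.

## What the phantom does and does not show

Passing the pipeline on the phantom demonstrates that the metrics are
exact (oracle-verified), that the DVH/constraint machinery is correct on
closed forms, and that the analysis *recovers an injected causal
mechanism*: when near-target underestimation is injected into half the
fractions, those fractions violate more often, and the ring analysis
localizes the responsible error to the 0–15 mm ring (significant
inner-ring separation with more-negative VOL_DIFF among violators,
non-significant outer ring).  It does not validate any claim about real
DIR algorithms, real organ motion statistics, or real optimizer behavior:
organ shapes are parametric solids, the dose model has no beam geometry,
the surrogate optimizer is ideal by construction, and cohort-level
percentages from the phantom are properties of the chosen generator
settings, not estimates of clinical rates.

## Problem sizes

Defaults are scaled for interactive use: the demo cohort is 3 patients ×
3 fractions; the analysis cohorts used by the acceptance script are 12×3
(two error profiles, full geometric tables) and 20×3 (mechanism recovery,
rings only).  Oracle tests run on 16³–32³ grids; continuum-geometry checks
on 0.5 mm grids up to 160³.
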