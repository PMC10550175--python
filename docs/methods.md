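# Methods

## Voxel model and conventions

All volumes are boolean occupancy masks on a regular 3D lattice: `True` =
material present (undrilled). Indices are 0-based, samples sit at voxel
centers, and the world position of voxel `(i, j, k)` is
`origin + (i, j, k) * spacing`, in centimetres. The default discretization
of the tooth region is 90 × 135 × 90 at 0.015 cm isotropic spacing, i.e. a
1.35 × 2.03 × 1.35 cm bounding box with the long axis vertical.

Drilling only removes material, so the ideal outcome and every actual
outcome are subsets of the initial tooth mask; violations raise validation
errors naming the offending voxel count. Classification is restricted to the
initial tooth mask — voxels that were never tooth material carry no
information about drilling quality and are ignored. This makes the
conservation identity `TP + TN + FP + FN = |initial|` exact.

## Scoring

Precision `P = TP/(TP+FP)` and sensitivity `S = TP/(TP+FN)` are rescaled
linearly with anchors 0.95 and 0.2 and combined into
`D = (1 − (1.5·S~ + P~)/2.5)·15`, algebraically identical to the closed form
in raw counts. Two deliberate numerical choices:

* **No clamping.** Outcomes outside the empirical component windows
  (`P ∈ (0.96, 0.995]`, `S ∈ (0.2, 1)`) produce `D` outside [0, 15] and a
  logged warning. Clamping would break the exact equivalence of the two
  forms, which the suite verifies to 1e-9 relative tolerance on 10,000
  random count triples.
* **Degenerate tallies are errors.** `TP+FP = 0` (no material retained) or
  `TP+FN = 0` (nothing should remain) leave the components undefined; these
  raise a typed error rather than returning a sentinel. Realistic outcomes
  always retain material.

The metric suite reports 25+ standard binary-classification metrics from the
same 2×2 table; per-metric undefined values are reported as missing with a
reason, never silently as 0.

**Essential-outcome selection** partitions the observed score range into `k`
equal-width bins and takes, from each nonempty bin, the sample nearest the
bin center (ties → lowest index); empty bins are filled with the globally
unused sample nearest their center. The tie-break and empty-bin rules are
this package's choice; the underlying goal is uniform coverage of the range
with distinct samples.

## Surfaces and voxelization

Sphere sets are discretized with either a **hard union** (a voxel center is
occupied iff inside some sphere; exact, used by the synthesis module) or a
**metaball field**: per sphere a compactly supported polynomial falloff
`((1 − (d/R)²)/(1 − (r/R)²))³` with support `R = 1.5·r`, summed over spheres
and thresholded at 1, so an isolated sphere's iso-surface is exactly its
nominal boundary while overlapping spheres blend smoothly. The kernel and
threshold are this package's choice; both modes are exposed.

Surface extraction runs lookup-table marching cubes (scikit-image) on the
binary field smoothed with a narrow Gaussian (σ = 0.8 voxels, iso-level
0.5). The smoothing recovers sub-voxel surface placement: on an analytic
sphere the mesh area error is below 1% and the enclosed-volume error
decreases with spacing (−0.9% at 0.03 cm, −0.09% at 0.015 cm), whereas
marching cubes on the raw 0/1 field plateaus near +8.6% area error. When
smoothing would erase features thinner than the kernel (e.g. a single-voxel
island), extraction falls back to the raw field so every nonempty mask
yields a closed mesh. All-true or all-false masks have no iso-surface and
return an empty mesh that callers must check.

## The synthetic phantom

The phantom is procedural; anatomical fidelity is a non-goal, fidelity of
the resulting score distributions is the goal. Geometry (proportional to the
grid extent): an outer crown ellipsoid whose shell is enamel; dentin filling
the inner crown, two tapered roots, and a sheath around the pulp cavity; a
pulp chamber ellipsoid with four canals descending into the roots; and the
ideal access cavity — a tapered shaft from the occlusal surface opening into
the chamber, exposing all four canal orifices. Tissues are realized as
labelled spheres on jittered lattices filling each region (radii slightly
above the lattice step, so the hard union is solid), with one explicit pulp
sphere per orifice so each orifice center is guaranteed to be material
inside the ideal cavity. Default sphere counts (enamel 1000, dentin 1700,
pulp 100) are scaled down 100-fold from the full-scale model's
100k/170k/10k composition to keep a phantom build near one second; counts
are configurable back up.

## Outcome simulation

An outcome is `occupancy − carved`. The carved region starts from the plan's
target (swept capsules along an explicit path, or the ideal cavity for the
nominal plan), expressed as a signed Euclidean distance field; it is dilated
by `overdrill_extent` (cm), the core-most `underdrill_fraction` of the
cavity (by distance to the cavity boundary) is retained, and the carve
boundary is jittered by smooth Gaussian-filtered noise of amplitude
`roughness` (cm, default 0.01). By construction `actual ⊆ initial` always
holds.

Series generation inverts score targets exactly through the phantom's
precomputed distance-field quantiles: a sensitivity target (truncated-normal
over (0.25, 0.995) by default, uniform as the alternative sampling target)
maps to the overdrill extent that removes the corresponding share of
should-remain voxels, and a precision target drawn uniformly from the high,
narrow (0.965, 0.995) window sets the retained cavity fraction. This keeps
generated component scores inside the empirically observed windows
(sensitivity wide, precision high and narrow) and makes a 240-outcome series
a sub-minute computation. A 240-outcome series spans an F1 range ≥ 0.5.

## Synthetic cohorts

Participant records (four condition groups: stereo/mono 3D rendering ×
aligned/misaligned hand-tool calibration) carry pre/post expert errors, six
trial scores, and a mean eye-tooth distance. Expert errors are **truncated
normals parameterized by their post-truncation moments** (parent parameters
solved numerically and cached): pre-test error (2.77, SD 1.19), post-test SD
1.56, pooled inverse learning gain mean −0.375 with zero-sum group offsets
preserving the between-group contrast pattern (−0.139, −0.350, +0.551,
−0.063). Means are linear, so the pooled gain mean is exact by
construction; the printed pre/post/gain SDs imply a within-subject
correlation of ≈ 0.1, so independent marginals are used. Moment-matched
truncation (rather than clipping at 0) is what makes the configured gain
mean recoverable: clipping would bias it by ≈ +0.15.

Suitability (pre-error vs day-1 simulator score) and transfer (real vs
simulator gain) correlations are imposed per group on the generating
latents via a Gaussian-copula construction, with defaults (0.41, 0, 0,
−0.39) and (0, 0.49, 0.27, 0.30) reflecting the observed direction pattern
of the four conditions. Trial trajectories interpolate between per-group
trial-1 and trial-6 means with the pooled improvement shape
(0, 0.45, 0.78, 0.78, 0.78, 1), plus participant-level (SD 0.55) and
trial-level (SD 0.35) noise; trial scores are floored at 0 (negligible
mass below). The zero-effect configuration (`CohortConfig.null()`) removes
all gains, offsets and correlations and is used to verify that the paired
one-tailed test's type-I error sits at 5% ± 1% over 10,000 replicate
cohorts.

What the generator does **not** emulate: learning-curve shapes beyond the
six-trial interpolation, non-normal or heteroscedastic error distributions,
rater-specific bias in the expert totals, and any real anatomical
variation. Passing tests therefore demonstrate correctness and calibration
of the analysis machinery, not empirical claims about real students.

## Study analytics

* Inverse learning gain `e_Δ = e₁ − e₀` (negative = improvement).
* IQR outlier filtering uses linearly interpolated quartiles and the
  standard 1.5·IQR fences; removed values are reported, and the analysis
  pipeline exposes a flag for whether subsequent tests use the filtered set.
* The paired one-tailed t-test (default direction: post lower) and Welch's
  unequal-variance t-test (fractional Welch–Satterthwaite df) return typed
  undefined markers on zero-variance input, never silent NaNs.
* Transfer analyses compute Pearson r/p per stratum (all, by rendering
  mode, by alignment, by group). "Initial simulator performance" is the
  mean of trials 1–3 (day 1) by default, with trial-1-only as an option,
  since both operationalizations are defensible.
* Angle differences wrap into [−180°, 180°] with round-half-even turn
  counting, so ±180° are fixed points; the calibration offset composes the
  hand-measured translation/rotation offsets with the wrapped difference.
* Mean eye-tooth distance averages the Euclidean cyclops-eye-to-tooth-hit
  distance over gaze samples that hit the tooth; no-hit trials are
  undefined, not 0.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed (phantom, plan,
series, cohort) and is bit-reproducible per seed. The validation suite uses
the quarter-resolution phantom (45 × 68 × 45 at 0.03 cm) for unit tests and
the full 90 × 135 × 90 phantom for the monotonicity and 240-outcome
end-to-end checks; calibration checks use 10,000 replicate cohorts of 40
participants. ICC is computed from the two-way random-effects mean squares
(ICC(2,1) absolute agreement by default, ICC(2,k) selectable), with an
independent ANOVA oracle and pingouin cross-check in the tests; Cohen's
kappa defaults to linear weights for ordinal 0–15 totals (unweighted
available); the IBMD uses natural logarithms, +1 offsets, and the 0/0 → 0
convention.

## Known limitations

* The phantom is one synthetic molar; scores on real CT-derived anatomy may
  occupy different component windows.
* The choice of implicit-surface kernel and threshold is not uniquely
  determined by the problem; both provided modes are documented and tested,
  and results for blended geometry depend mildly on the kernel.
* Whether per-surface categories or totals should feed the kappa between
  raters is ambiguous; the implementation accepts any integer score
  vectors and leaves the choice to the caller.
* The agreement statistics quantify consistency with an expert scale; they
  cannot establish clinical validity of the rubric itself.
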