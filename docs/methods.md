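# Methods

`hemipark` implements the analysis chain of a hemiparkinsonian-rat imaging
and gait study on synthetic phantom cohorts: dopamine-depletion severity
from FDOPA-PET, voxel-wise FDG-PET statistics with TFCE and permutation
FWE correction, and CatWalk-style gait statistics. This note records the
models, the defaults and why, and what the synthetic cohorts do and do not
show about real data.

## Imaging model

**Grids and preprocessing.** All volumes live on one shared grid (default
40 x 48 x 24 voxels of 0.38 x 0.38 x 0.82 mm, the reconstruction grid of
the small-animal protocol being emulated); no resampling is implemented,
and grid mismatches are errors. Smoothing uses a Gaussian kernel
parameterised by FWHM in mm (per-axis sigma in voxels =
`fwhm / voxel_size / (2 sqrt(2 ln 2))`). With a brain mask the kernel is
renormalised over in-mask support (normalized convolution), so no
intensity leaks across the brain edge — the alternative (zero-padded
smoothing) depresses rim voxels and would bias SUVR near the surface.
Maskless smoothing uses reflective boundaries, which conserves total
intensity exactly. Subjects with right-hemispheric injections are flipped
across the midline before any group statistic, so the lesioned hemisphere
is always left.

**SUVR.** Intensities are divided by the mean over a reference region —
cerebellum for FDOPA, whole brain for FDG — making all downstream
statistics invariant to injected dose and scanner calibration.

**Depletion severity.** `severity = 1 - (ipsi mean / contra mean)` over a
combined striatum + nucleus accumbens VOI (five sub-regions pooled
voxel-wise, i.e. count-weighted) on the cerebellum-normalised image: 0 for
a symmetric brain, 1 for complete ipsilesional signal loss. The
normalisation cancels algebraically in the ratio but is kept as part of
the procedure. Severity is computed on *unsmoothed* SUVR by default
(`severity_on_smoothed` flips this): on the few-voxel regions of the
procedural atlas, 1.5-mm smoothing mixes background into the VOI means and
attenuates the score multiplicatively; since the attenuation is monotone
it would not change correlation analyses, but the unsmoothed score is the
one that equals the planted severity (slope 1 against ground truth).

## Voxel-wise inference

**Statistics.** Group maps use the pooled-variance two-sample t
(df = n_a + n_b - 2; the 7 + 6 cohort gives df 11). Covariate maps use
Pearson r across subjects. Voxels with zero pooled variance get statistic
0 with a warning rather than an error, because permuted relabelings can
create such voxels legitimately.

**TFCE.** Threshold-free cluster enhancement integrates cluster extent and
height over a discrete ladder:
`TFCE(p) = sum_{h=dh..h_max} e_h(p)^E h^H dh`, with `e_h(p)` the voxel
count of the connected component containing `p` at threshold `h`, and
`dh = h_max / n_steps` computed per sign. Defaults E = 0.5, H = 2,
n_steps = 100, 6-connectivity — the canonical recommendations of the TFCE
method; all are exposed. Positive and negative parts are enhanced
separately. The inner loop is a numba-compiled flood fill that relabels
components from scratch at every threshold; it is verified against an
independent pure-Python brute-force implementation to 1e-9 relative on
random maps for E in {0.5, 1}, H in {1, 2}, connectivity in {6, 26}, and
against the analytic single-voxel limit h^3/3.

**Permutation FWE.** For each permutation (group relabeling, or covariate
shuffle for correlation maps) the statistic map and its TFCE are
recomputed and the image-wide maximum of each sign recorded. All distinct
relabelings are enumerated when there are at most 20,000 (the 7-vs-6
design has C(13,6) = 1716, so corrected p-values are exact multiples of
1/1716); otherwise 1,000 Monte-Carlo permutations are drawn and the
identity permutation is included in the null, so the smallest attainable
corrected p is 1/(n_perm + 1). By default each sign is tested against its
own null maxima at the nominal alpha, which controls the family-wise error
at alpha *per sign* (roughly 2 alpha across both signs); the `two_sided`
option tests the combined map against the null of max(|.|), whose
family-wise error is alpha by construction — this is the variant whose
calibration the acceptance suite certifies on 200 null cohorts.
Significant clusters at the stricter threshold (p < 0.01 by default)
become VOIs named by the majority atlas region they overlap, and their
mean SUVR feeds the brain-behaviour correlations.

**r-scale enhancement.** Correlation maps are enhanced on the r scale
directly; an `r_to_t` toggle applies the monotone t transform first.
Because permutation inference compares like with like, the choice affects
the interplay of cluster extent and height, not validity.

## Synthetic cohorts

The generator plants known structure so every stage can be tested against
ground truth; it makes no attempt at anatomical realism or PET physics.

* **Atlas** — mirrored ellipsoid pairs (striatal and accumbens sub-regions,
  caudal striatum, rostral forelimb area, lateral posterior thalamus,
  midbrain locomotor region, cerebellar lobule V) plus a midline
  cerebellum, embedded in an ellipsoidal parenchyma. Pairs have exactly
  equal voxel counts, so a lateral flip maps each region onto its partner.
* **Cohort** — 7 lesioned + 6 sham by default; lesioned severities drawn
  Uniform(0.3, 0.9) (a continuum from mild to near-complete depletion, as
  needed for correlation analyses), shams fixed at 0; injection side
  randomised per animal and recorded.
* **FDOPA** — striatal/accumbens uptake 2.5 against background 1.0; the
  whole ipsilesional striatal signal is scaled by (1 - severity), so
  severity 1 zeroes the VOI and the recovered statistic is exactly 1.
  Multiplicative Gaussian noise (default sd 5%), optionally spatially
  smoothed (`noise_smooth_fwhm_mm`) to mimic reconstructed-PET noise
  correlation.
* **FDG** — a fixed baseline template with per-region multiplicative
  shifts `1 + slope x severity`; default slopes are hypometabolic
  ipsilesionally (medial striatum -0.15, RFA -0.20, lpTh -0.22) and
  hypermetabolic contralesionally (caudal striatum +0.20, MLR +0.25,
  cerebellar lobule V +0.15), reproducing the ipsi-hypo / contra-hyper
  imbalance the method is meant to detect.
* **Gait** — strict diagonal sequence (CF+IH alternating with CH+IF).
  Per-paw swing/stance/stride/print-area targets are linear in severity;
  within a run they are constant, so recomputed parameters equal targets
  exactly and all emitted runs pass the compliance rule. Steps per paw
  derive from the 39-cm walkway and the realised stride, which makes the
  number of steps rise and cadence fall with severity. Baselines (swing
  0.10 s, stance 0.25 s, stride 16 cm, print area 1.8 cm^2) give a sham
  average speed of ~46 cm/s; slope signs follow the expected
  severity-correlation pattern (durations and ipsilesional-hind print area
  up, stride and speeds down), with the contralesional forelimb carrying
  the largest swing-duration slope. Between-animal residual SDs are set so
  the planted correlations of the strong effects are ~0.85 — the upper
  range of what such studies report — which makes the sign pattern a
  stable property of the design rather than a coin flip at n = 13.

What passing tests on these phantoms show: the *statistics* are correct
(exactness of the enumeration, FWE calibration, df structure, recovery of
planted effects with the right sign). What they do not show: robustness to
registration error, partial-volume and spill-over effects, anatomically
realistic spatial correlation, kinetic or attenuation artefacts, or
instrument-specific gait detection noise — none of which are simulated.

## Gait analysis

Stance = lift - contact; swing = next contact (same paw) - lift; stride =
Euclidean distance between successive placements; swing speed =
stride/swing (so swing_speed x swing_duration = stride exactly, per step);
body speed per paw = stride / (stance + swing). Cadence = total contacts /
run duration. Average speed = displacement of the centroid of paw contact
positions over the centroid's contact-sampling window; the instrument
vendor's exact definitions of "average speed", "body speed" and "speed
variation" are proprietary, so these estimators are package choices,
config-exposed and recorded in output metadata. Compliance follows the
published rule (<= 5 s, speed variation <= 60%), with variation estimated
as 100 (v_max - v_min)/v_mean over mean body speeds in the thirds of the
run. Aggregation is steps -> run -> animal, weighting runs equally.

The two-way mixed ANOVA (between: treatment; within: paw) is computed from
the exact split-plot decomposition: treatment is tested against
subjects-within-groups, paw and interaction against
paw x subjects-within-groups. The decomposition is additive for unequal
group sizes provided every animal has all four paw levels (13 animals in
2 groups give df (1,11) and (3,33)); incomplete designs are errors, not
imputed. It is cross-checked against pingouin in the test suite. Post hoc
comparisons (between-group t per paw; within-group paired t per paw pair)
default to Holm correction per family — the omnibus publication this
mirrors names no post hoc scheme, so the choice is explicit and
configurable. Correlation p-values use
`t = r sqrt(n-2)/sqrt(1-r^2)` at n-2 df, exposed as `p_from_r` so printed
(r, n) pairs can be validated directly.

## Numerical choices and limitations

* float32 storage (NIfTI), float64 arithmetic throughout.
* TFCE's discrete ladder makes enhanced values depend mildly on `n_steps`
  and on each map's own h_max (through dh); monotonicity in the statistic
  holds exactly for changes that leave the ladder fixed.
* Problem sizes in the test and acceptance runs are scaled to the method:
  calibration uses 200 null cohorts on a 16 x 16 x 12 grid with 250
  permutations and 25 TFCE steps; exhaustive and detection runs use the
  full default grid (~20k brain voxels) with 25 steps. Step count trades
  integration resolution against cost and does not affect validity of the
  permutation test.
* Degenerate inputs: empty reference masks, non-positive reference means,
  constant covariates, zero-variance paired differences, overlapping
  footfall events and incomplete ANOVA designs all raise with specific
  messages; identical paired vectors return t = 0, p = 1 (no effect)
  rather than an error.
* The pipeline is deterministic given (config, seed): results JSON is
  byte-identical across reruns, and every output embeds the seed and a
  hash of the analysis-relevant config.
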