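# Methods

## The model

`ratssm` analyses structural covariance of gray matter in small-animal MRI
with the Scaled Subprofile Model (SSM). The data are per-subject
voxel-based-morphometry gray-matter density maps, assumed strictly positive
inside a shared analysis mask. SSM treats each map as a multiplicatively
scaled regional profile,

    gm_sv = g_s * exp(m_v + r_sv),

where `g_s` is a subject-global scaling factor, `m_v` the group-mean log
profile and `r_sv` the subject-by-voxel residual of interest. Taking natural
logs and removing the subject means and then the voxelwise means of the
row-centered matrix leaves `r_sv` double-centered: every row and column mean
is zero, and any per-subject rescaling of the input volumes (calibration,
global atrophy, intensity units) is absorbed exactly into the removed row
means. The residual matrix is then decomposed by SVD,

    R = U S Vt,

giving regional covariance *patterns* (rows of `Vt`, unit-norm voxel
weights), subject *scores* (`U S`, the per-subject expression of each
pattern) and variance fractions `s_k^2 / sum(s^2)`. Conventions the
decomposition does not determine are fixed and documented: patterns are
oriented so the largest-|weight| voxel is positive; scores carry the
singular values; components with `s_k^2 <= 1e-12 * sum(s^2)` are dropped.
Row-then-column centering is used; the two orders commute for complete
matrices (asserted by test).

## Component selection and the age composite

The age-group indicator (young = 0, aged = 1) is regressed on subject scores
for every subset of the first 8 components up to size 4, plus the
intercept-only model. Each fit is scored with the small-sample-corrected
Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),

where `k` counts the intercept plus slopes (a convention; a constant offset
in `k` does not change the ranking within a fixed model family). The
minimum-AICc subset wins; ties break toward the smaller subset, then
lexicographically. The winning coefficients define the *composite pattern*
(coefficient-weighted sum of the selected patterns) and *composite scores*
(the same combination of score columns), re-oriented so the aged group's
mean composite score exceeds the young group's. Group discrimination is
summarised by `R^2` and `F = (R^2/p) / ((1-R^2)/(n-p-1))` on `(p, n-p-1)`
degrees of freedom. Head-size effects are checked by a hierarchical
regression entering estimated total intracranial volume (eTIV, the summed
gray + white + CSF segment volumes times voxel volume) first and the
composite score second; the increment is tested with
`F_change = dR^2 / ((1-R^2_full)/(n-3))` on `(1, n-3)` df.

**A caution on the selection rate.** All-subsets minimum-AICc selection is
intrinsically liberal at n = 20: a spurious component displaces the true
model whenever it reduces the remaining RSS by about 13% (the AICc
difference depends only on the RSS ratio), which the best of 7 orthogonal
noise components achieves for the majority of datasets *regardless of effect
size*. On strong-effect synthetic cohorts the winning subset always contains
component 1 but equals {1} exactly in only ~30% of seeds. Users should read
the candidate table (reported alongside the winner) rather than trust the
arg-min alone; a Burnham–Anderson style inspection of models within a few
AICc units is advisable at this sample size.

## Bootstrap reliability z-maps

Voxelwise reliability of the composite weights is estimated by resampling
subjects with replacement *within* age group (preserving the two-group
design), rerunning the log/centering/SVD chain on each replicate, refitting
the composite coefficients with the component-subset indices frozen to the
point estimate (re-selecting per replicate would add subset-switching noise
to the voxel weights), and sign-aligning each replicate composite to the
point estimate. The z statistic is the point-estimate weight divided by the
bootstrap standard deviation (a bootstrap-mean numerator is a documented
switchable alternative). Replicates in which a group collapses to one unique
subject are redrawn and counted. The standard deviation is floored at 1e-12;
voxels at the floor are flagged and their z capped. Maps are thresholded
two-sided at |z| >= 3.5 with a 50-voxel extent rule; positive and negative
voxels are clustered separately with 6-neighbor (face) connectivity
(configurable), so opposite signs can never merge. Cluster labels are
deterministic (size-descending, then peak coordinate), and each cluster
reports its extreme z and location.

## Swim-task scoring

Morris swim trials are scored with CIPL (corrected integrated path length,
equivalent to cumulative search error): the trapezoidal time-integral of the
animal's distance to the platform *edge* (escape happens at the edge; a
center-distance variant would only add a constant per unit time), minus the
same integral for an ideal straight approach from the release point at the
animal's own mean swim speed, floored at zero. Units are metre-seconds. A
stationary animal has mean speed zero, so its ideal term equals its actual
integral and CIPL degenerates to 0 — the velocity correction is undefined
rather than informative there, and the case is flagged in the docstring.
Trials ending at timeout integrate over the full recorded duration. The
learning index is `(day1 - day4) / (day1 + day4)` of the per-day mean CIPLs,
in [-1, 1] for non-negative means.

## Cohort statistics

* **Mann–Whitney U** (visual-task group comparisons): midranks for ties, U
  reported as `min(U_a, U_b)`, exact two-sided p by enumeration when both
  n <= 12 with no ties, otherwise the tie-corrected normal approximation
  (no continuity correction). `u_from_mean_rank` reconstructs U from a
  reported per-group mean rank, rejecting unattainable rank sums.
* **Mixed-design ANCOVA** (spatial-task learning): split-plot strata. The
  between stratum regresses subject means on the covariate (mean visual-task
  performance) then group, testing group on `(1, n-3)` df. The within
  stratum regresses subject-centered responses on day, day x covariate and
  day x group contrasts, testing day and the interaction on
  `(d-1, (d-1)(n-3))` df. Including day x covariate in the within stratum is
  the SPSS-style convention and yields the error df `3(n-3)` (= 51 at
  n = 20, d = 4); omitting it would give 54. No sphericity correction is
  applied. A zero-variance covariate falls back to a plain mixed ANOVA with
  a warning.
* **Score–behavior regression**: Pearson r between composite scores and
  learning indices, `R^2 = r^2`, `F = R^2 (n-2)/(1-R^2)` on `(1, n-2)` df.
* **Shapiro–Wilk gate**: normality is checked at alpha = 0.05 and failures
  are *warnings only* — the analysis never switches method automatically,
  mirroring a confirmatory use of the test.

## The synthetic cohort generator

The generator exists so every stage is testable without animal data. It
emulates a two-group design (default 10 young + 10 aged) on a 32 x 32 x 24
grid of 150-um voxels with an ellipsoidal "brain" mask (~8,200 voxels).

Imaging: log gray matter is `ln(baseline) + ln(scale_s) + score_s * P_v +
noise`, exponentiated, so positivity is structural and the SSM centering
recovers exactly a rank-one signal plus noise. The pattern `P` is four
7-voxel cubes (343 voxels each, two negative = age-reduced, two positive =
age-increased), all comfortably above the 50-voxel extent threshold; the
generator rejects geometries leaving fewer than 60 in-mask voxels per
block. Subject scores are Gaussian with group means separated by
`pattern_effect` (the per-voxel group log-difference inside blocks, since
block amplitude is 1): default 0.1 against a voxel noise SD of 0.02 (the
five-to-one design condition) and a within-group score SD of 0.02, chosen so
group score distributions separate cleanly, as strong published
single-component findings imply. Global scales are lognormal (SD 0.1);
synthetic eTIV is lognormal around 2,000 mm^3 (a realistic rat intracranial
volume); ages are uniform on the published ranges (9.6–11.7 and 24.1–26.2
months).

Behavior: each trial is a circling search phase around the pool (radius
0.9 m, platform radius 0.06 m at 0.45 m from center, release at 0.8 R, swim
speed 0.25 m/s, 4 Hz sampling, 60 s timeout) followed by a straight
approach. The circling time is found by bisection so the trial's CIPL hits a
target; targets decay geometrically across days from a day-1 level of
18 m*s (inflated by `1 + behavior_age_deficit` for aged subjects — a
multiplicative deficit, which shifts performance level without biasing the
learning index) to the level implied by a per-subject target learning index.
That index is linear in a latent ability constructed by Gram–Schmidt so its
in-sample correlation with the true pattern expression equals
`behavior_coupling` exactly (default -0.5); the realized score–learning
correlation then differs only through trial-level jitter (lognormal, SD 0.08
on targets). Visual-task day means are generated as lognormal summaries with
a deficit-scaled group shift, not as paths.

What the generator does **not** emulate: anatomy (blocks, not structures),
registration/segmentation error, spatially correlated or heteroscedastic
noise, wall-hugging/thigmotaxis and other real search strategies, floor
effects in very fast trials. Passing recovery tests therefore show the
estimator chain is correct under its own assumptions, not that real rat
data would behave this way.

## Numerical and design choices

* Smoothing interprets a kernel width as FWHM (SPM convention;
  `sigma = FWHM / (2 sqrt(2 ln 2))` per axis in voxel units), with
  reflective boundaries so total intensity is conserved to 1e-6 relative on
  small phantoms; kernels under 0.1 voxel warn and return the input.
* The analysis mask requires positivity in *every* subject, guaranteeing the
  log transform is defined; masked voxels are flattened in C order, the
  single linear order used for patterns, z-maps and saved volumes.
* Voxel indices are 0-based; world coordinates come from the stored affine
  (voxel size on the diagonal by default).
* Degenerate inputs are rejected with diagnostics (non-positive voxels name
  the subject and coordinate; empty masks, singular candidate designs,
  zero-variance covariates, constant samples, undefined learning indices all
  raise or warn as documented above).
* Problem sizes in the test and acceptance runs — 100-seed selection loops,
  200 bootstrap iterations, 50-sample path fixtures against 200,000-point
  integration oracles — were chosen so the whole chain runs in seconds on
  one CPU while keeping Monte-Carlo error well inside the asserted margins;
  the bootstrap default for real analyses remains 500 iterations.

## Known limitations

* Minimum-AICc over-selection at small n (see above) is a property of the
  published procedure, reproduced faithfully, not corrected.
* The bootstrap freezes the component subset; subset-selection uncertainty
  is therefore not propagated into the z-maps.
* CIPL assumes the tracked path is the swim path (no smoothing of tracker
  noise) and measures distance to the platform edge; WMAZE/ANY-maze exports
  may operationalize either choice differently.
* No anatomical labeling: clusters are reported by voxel coordinate only.
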