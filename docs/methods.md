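# Methods

This note documents the models, algorithmic choices and limitations of
`wmtraj`, in the order the pipeline runs.

## Trajectories and distance

A trajectory is one participant's daily adaptive dual n-back scores,
one value in [1, 4] per session, 7–15 sessions depending on the source
study, with possible early truncation (dropout) and isolated holes.
Trajectories are padded to the cohort maximum T (15 by default) and
never imputed.  A participant needs at least 3 observed sessions to be
clusterable; rows below that are excluded with a warning (with fewer
points the missing-data adjustment below becomes degenerate).

The distance between two trajectories is the Euclidean distance over
their m jointly observed sessions multiplied by sqrt(T/m).  The
inflation factor puts short and long trajectories on a common scale:
it treats the observed sessions as a representative sample of the full
trajectory, which is reasonable for missing tails (truncation) and
random holes, but would bias distances if missingness depended on the
score itself (e.g. participants skipping sessions after bad days).
Pairs with no common observed session are *incomparable* (infinite
distance); assignment skips such seeds and errors only if every seed is
incomparable.

## Longitudinal k-means

Clustering alternates nearest-seed assignment with per-session
recomputation of seeds as observed-member means until no assignment
changes (a fixed partition) or `max_iter = 200` iterations pass
(non-convergence is a warning, not an error; observed runs converge in
well under 20 iterations).  Details:

* **Initialization** is k-means++: first seed uniform over
  trajectories, each next seed drawn with probability proportional to
  squared distance to the nearest chosen seed; seeds start as copies of
  actual trajectories and become free per-session means after the first
  update.
* **Ties** in nearest-seed assignment go to the lowest cluster index.
* **Emptied clusters** are re-seeded from the trajectory currently
  farthest from its own seed.
* **Restarts**: the EM run is repeated 20 times on independent
  substreams of the user seed; the restart with the highest variant-1
  Calinski–Harabasz score wins (first on ties, so runs are
  reproducible).
* **Label convention**: clusters are relabeled by ascending mean seed
  level, so cluster 1 is always the lowest-performing trajectory and
  cluster k the highest.  This makes labels comparable across restarts,
  seeds and halves.
* **Order invariance**: all RNG-driven choices are made in a canonical
  (sorted-id) participant order, so permuting input rows changes
  nothing but row order in the outputs.

## Validity criteria and choice of k

For each k in 2..6 the sweep records, oriented so higher is better:

* CH variant 1: (Tr B / Tr W) · (n−k)/(k−1) — the classic form, used
  for restart selection and as the primary criterion;
* CH variant 2: (Tr B / Tr W) · (n−1)/(n−k); variant 3: the raw trace
  ratio — documented alternates from the longitudinal-clustering
  literature, reported but never used for selection;
* Ray–Turi: −(mean within-cluster squared scatter / smallest squared
  seed gap);
* Davies–Bouldin: −(mean over clusters of the worst
  (compactness_i + compactness_j) / seed-gap ratio).

Tr W sums squared member-to-seed distances; Tr B sums size-weighted
squared seed-to-grand-mean distances, all with the sqrt(T/m)-adjusted
distance.  Degenerate configurations produce sentinels with warnings
(+inf CH when W = 0; −inf Ray–Turi/Davies–Bouldin for coincident
seeds).  Each criterion is z-scored across the k range (a single-k
sweep standardizes to 0 by convention).  Partitions whose smallest
cluster is below 10% of the cohort are flagged unbalanced.  The
*recommendation* is the unflagged k with the best mean standardized
criterion; the choice is reported, never silently applied — mirroring
how the number of trajectories is chosen by inspection in practice.

Under labels independent of the data, CH variant 1 is F(k−1, n−k)
distributed, which the tests exploit as an exact null oracle.

## Split-half cross-validation

Halves are formed by parity of the 1-based file-order enumeration
(recorded in outputs for audit).  Each half is re-clustered at the
full-data k with the same restart budget; the held-out half is
assigned to the trained seeds by nearest distance (re-clustering the
test half is available as an option).  Half labels are aligned to the
full-data labels by a Hungarian assignment on the k×k contingency
table.  Concordance is reported three ways: per half for train
members, per half for test assignees, and combined — a participant
counts as concordant only if *both* halves place them in their
full-data cluster.  The combined count is therefore the strictest of
the three readings.

## Symptom indices

Each instrument's raw total is z-standardized against its cohort
pre-training mean/SD (ddof = 1); post and follow-up scores use the same
pre norms so change is measured on a fixed scale.  The anxiety index is
the mean of available z(STAI), z(PSWQ), z(SAS-2); depression of z(BDI),
z(RRS); the general index is the mean of whichever of the two exists.
All five instruments score higher = worse, so improvement = pre − post
with positive meaning symptom reduction.  Indices use whatever
components a study administered (maximizing data use); improvements are
missing, not errors, when a side is absent.  Alternative references
(published norms) can be passed explicitly; indices are invariant to
affine rescaling of any instrument as long as norms are recomputed.

## Cluster statistics

Change scores and baseline predictors are compared across clusters with
classic one-way between-groups ANOVAs (η² = SSB/SST; Welch correction
deliberately off so degrees of freedom match the one-way reporting
convention, available upstream if needed).  Tukey–Kramer HSD p-values
come from the studentized range distribution; for the three outcome
indices the family alpha 0.05 is Bonferroni-divided by 3 before
flagging, while the exploratory baseline predictor screen is
uncorrected by design.  Gender enters its ANOVA numerically coded.
Within-cluster pre-post change uses a paired t-test with
d = mean(diff)/sd(diff).

## Mediation model

The three-variable path model (X = baseline CDT score, M = cluster
label as an ordered numeric 1 < 2 < 3, Y = anxiety improvement) is
estimated by maximizing the trivariate-normal likelihood implied by
M = aX + e1, Y = bM + c′X + e2, with free means and residual
variances (9 parameters — saturated for the first and second moments).
With the `fiml` policy each partially observed case contributes the
marginal normal likelihood of its observed subset; `listwise` drops
them.  Variables are z-scored internally so paths are standardized
coefficients.  Standard errors are observed-information (numerical
Hessian at the optimum); Z = coef/SE with normal reference.  The model
is compared with an independence baseline (means and variances only,
6 parameters; with a single exogenous variable there are no exogenous
covariances to add) by likelihood-ratio chi-square on 3 df — the df is
computed, not hard-coded.  With complete data the ML paths equal the
two OLS regressions' standardized coefficients, which the tests verify
to 1e-6.  The indirect effect ab gets a first-order delta SE,
sqrt(a²SE_b² + b²SE_a²), and optionally a percentile bootstrap over
cases.  Treating the cluster mediator as equally spaced is an
assumption; `dummy_mediator_sensitivity` re-estimates both equations
with indicator-coded clusters on complete cases as a check.  Null
calibration is slightly liberal at small n (normal rather than t
reference), on the order of 5–7% rejection at nominal 5% for n ≈ 80.

## Synthetic cohort generator

The generator exists so every stage can be tested against known ground
truth; its defaults are the study conditions used throughout the tests.

* **Classes**: three latent learner types drawn i.i.d. with
  probabilities (0.312, 0.375, 0.313).  Mean curves are parametric
  templates through anchor levels: class 1 a quadratic hump (1.39 at
  session 1, 1.76 at session 8, 1.28 at session 15 — no net learning);
  class 2 linear (1.86 → 3.34); class 3 exponential saturation toward
  the task ceiling of 4 (2.46 → 3.70).  Anchors constrain the curves;
  the functional forms (quadratic/linear/exponential) are the
  generator's own choice of smooth shapes matching "no improvement /
  steady / saturating" learner descriptions.
* **Noise**: additive Gaussian per session (sd 0.45), clipped to
  [1, 4].  Real adaptive-staircase scores are discrete-ish and
  autocorrelated; i.i.d. Gaussian noise is a simplification, so
  passing recovery tests show the pipeline works under the planted
  model, not that real cohorts are this clean.
* **Studies**: six blocks (sizes 11/13/20/13/24/15, durations
  8/15/15/10/14/7) each with its own questionnaire battery, cognitive
  tasks, follow-up availability and demographic profile, so index
  construction and FIML face realistic block-wise missingness.
* **Dropout**: a fraction drawn uniformly from [0.08, 0.20] of
  participants have their trajectory truncated at a uniform random
  session ≥ 3.  Dropout is independent of class and score
  (missing-completely-at-random); informative dropout is not modeled.
* **Outcomes**: anxiety change per class (−0.208 ± 0.513, 0.0 ± 0.50,
  0.193 ± 0.478 on the index scale; the middle class is interpolated
  between the outer two, as only those are pinned), follow-up analogues
  (−0.270 ± 0.825, 0.05 ± 0.60, 0.380 ± 0.431), class-independent
  depression change (0 ± 0.5), CDT baselines (1.03 ± 1.09,
  1.38 ± 0.83 interpolated/pooled, 1.73 ± 0.447) and flanker
  interference (79 ± 32.7, 78.4 ± 35.7, 41.2 ± 28.1).
* **Questionnaire back-construction**: latent index values (pre ~
  N(0, 1), post = pre − change) are mapped to raw totals through fixed
  reference norms per instrument plus small instrument-specific noise
  (sd 0.15).  Simulating at the index scale and inverting the
  standardization is deliberate — the analysis consumes indices, not
  item responses — so instrument-level psychometrics (reliability,
  floor effects) are out of scope.
* An optional `study_baseline_shift` adds per-study index offsets
  (default 0) to emulate pre-selection differences between source
  studies.

Everything is reproducible bit-for-bit from `rng_seed`; the planted
class of each participant is stored for recovery testing only and never
read by the inference modules.

## Problem sizes used in the test suite

The acceptance-style checks run the pipeline at the cohort's natural
size (96 × 15, 20 restarts, k = 2..6) across 20 generator seeds;
enumeration oracles use n ≤ 8 complete-data instances; mediation
recovery uses 200 replicates at n = 500; null calibrations use
150–2000 replicates.  These sizes give stable Monte-Carlo estimates
while keeping the full suite in the minutes range.

## Known limitations

* No growth-mixture or time-warping alternatives to k-means; cluster
  shapes are whatever the seeds converge to.
* The sqrt(T/m) adjustment assumes non-informative missingness.
* The mediator is treated as ordered numeric in the main mediation
  model; the dummy-coded sensitivity check is listwise-only.
* FIML assumes joint normality; the cluster label is discrete, so the
  likelihood is a working approximation (the same one implied by
  fitting such models with normal-theory SEM software).
* The generator's outer-class parameters are pinned to reported
  summary statistics of real training cohorts, but the middle class
  and the functional forms are interpolations; conclusions about real
  data should rest on the method, not on the generator's realism.
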