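# Methods

This note documents the statistical machinery of `atrophytwin`: the models,
the synthetic-data generators, the numerical conventions, and the design
choices made where the problem was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Data model

A `ScanTable` is a long-format table of MRI scans (subject, group MS/control,
sex, age at scan in decimal years, intracranial volume (ICV) and thalamic
volume in mm^3) joined to one covariate row per subject (sex, baseline
normalized thalamic volume, baseline ICV, age at entry, clinical-onset age
and years of disease-modifying-therapy (DMT) exposure at entry; the last two
are zero for controls). The response throughout is the normalized thalamic
volume `thalamus / ICV * 1000`, a dimensionless quantity around 9-10 in
adults that is invariant to global head-size scaling.

Validation rejects non-positive volumes, thalamus >= ICV, duplicate
(subject, age) pairs (the models index observations by age), controls with
nonzero disease covariates, clinical onset after study entry, and a supplied
`norm_thalamus` column inconsistent with the raw volumes beyond 1e-6
relative. The age filter retains scans with 16 <= age <= 90 inclusive
(younger scans confound atrophy with brain growth); augmented rib-bone
records are exempt because their ages exceed the window only by the
augmentation offset.

## 2. Cross-sectional normal-aging fit (MARS)

The cross-sectional fit regresses normalized thalamic volume on age, ICV and
sex with multivariate adaptive regression splines: a greedy forward pass adds
reflected hinge pairs `max(0, x-c)` / `max(0, c-x)` (interaction degree up to
3: age x ICV x sex), and a backward pass prunes terms to minimize

    GCV = (RSS/n) / (1 - C(M)/n)^2,  C(M) = #basis functions + d * #knots

with knot penalty d = 3 when interactions are allowed. Knot candidates are
observed values on a stride of ceil(n/100), which bounds the forward search;
ties break on first encounter, so the fit is deterministic and invariant to
row order. Sex enters as a 0/1 indicator (linear factors only). The
implementation is classic forward/backward MARS written for this package; no
attempt is made to match any particular historical basis, only the fitted
curve's shape.

## 3. Rib-bone augmentation

Each observed control scan at age `a` with value `y` spawns records at
`a + k`, k in {-2, -1, 0, 1, 2} years, with value `y + [f(a+k) - f(a)]`,
where `f` is the MARS fit with the subject's ICV and sex held constant. The
offset-0 record is the observation itself. Anchoring on the observed value
(not the model prediction) preserves between-subject variance; the model
contributes only the local age slope. No noise is added by default — the ribs
are deterministic; optional Gaussian noise injection supports sensitivity
analyses. When a subject has several true scans, colliding augmented ages
keep the record derived from the nearest observed scan.

Augmentation agreement is validated on held-out repeat scans by pairing each
observed repeat with the same subject's nearest augmented age (within 0.5 y)
and computing ICC(A,1) and the repeated-measures correlation.

A measured caveat (see `notes` in the acceptance experiments): because the
MARS surface is piecewise linear, its derivative is a step function, and the
deterministic ribs carry that local slope error into the longitudinal fit as
a systematic shape perturbation of order +-0.05-0.08 around slope breaks.
The deviation-age recovery experiment therefore fits the raw cohort
directly; augmentation fidelity is verified separately (exactness when the
generating truth lies in the model family, monotone ICC decay with injected
noise).

## 4. Penalized spline mixed model

### 4.1 Form

    Y_ij(t) = mu(t) + mu_MS(t) MS_i + X_ij beta + u_i + eps_ij,
    u_i ~ N(0, sigma_b^2),  eps_ij ~ N(0, sigma^2)

Each smooth is `F(t) alpha + Z(t) u` with `F` a fixed polynomial part and `Z`
a penalized block whose coefficients are iid `N(0, tau^2)` after an exact
linear reparameterization of the penalty. The smoothing parameter is the
variance ratio `lambda_s = tau^2/sigma^2`, estimated by ML or REML.

### 4.2 Bases and penalties

Ages are affinely scaled to s in [0, 1] over the training range before any
basis is built (keeps penalized columns O(1)). Interior knots default to 15
age quantiles, capped at min(n_distinct/4, 35).

* `cubic_tpf`: fixed {1, s, s^2, s^3}; penalized truncated powers
  `(s - t_j)^3_+` in raw per-knot coordinates (the classic "random TPF
  coefficients" smoother).
* `cubic_bspline`: same fixed part; penalized block = clamped cubic B-spline
  design with the polynomial component projected out, kept in native knot
  order. The two cubic bases span the same function space but smooth in
  different coordinate systems, so their penalized fits differ.
* `natural_tpf` / `natural_bspline`: fixed {1, s}; the natural (restricted)
  spline space — linear beyond the boundary knots — constructed two ways
  (Harrell restricted-cubic TPF columns; B-splines constrained to vanishing
  2nd/3rd boundary derivatives) and then standardized to the canonical
  age-weighted orthonormal basis of the shared span. The two
  parameterizations therefore produce numerically identical fits under every
  penalty, which is the behavior the twelve-structure comparison exhibits for
  the natural rows.
* Penalties: `toep1` is an iid ridge on the block coefficients (a TOEP(1)
  G-side matrix: common variance, zero off-diagonals). `pspline` penalizes
  squared first differences of adjacent coefficients; the penalty is
  reparameterized to iid form through the eigendecomposition of D'D, and the
  one-dimensional null direction (a common shift) is constrained to zero so
  the fixed-effect structure is identical across penalty types. `rsmooth` is
  Ruppert-Wand-Carroll radial smoothing: the penalized block is replaced by
  `|s - t_j|^3` columns scaled by Omega^{-1/2}, Omega_jk = |t_j - t_k|^3;
  the basis enum then affects only the fixed polynomial part.

### 4.3 Interaction smooths

The MS x age-spline interaction (and any covariate x spline interaction) adds
a group-difference smooth. Its fixed part keeps only the group offset and
group x age trend ({MS, MS*s}); all higher-order difference curvature lives
in a penalized block built from the *local* (unprojected) B-spline columns
and orthogonalized against the block's own fixed columns. Two reasons,
both measured during development:

* local support means a difference smooth fitted only where one group has
  data shrinks to zero outside that support, instead of extrapolating a
  global polynomial residual into the young-age region where the onset is
  detected;
* the orthogonalization guarantees the unpenalized line carries the entire
  low-order group difference, so coefficient shrinkage cannot bias it.

The fully duplicated fixed polynomial ({MS, MS*s, MS*s^2, MS*s^3}) remains
available as `ms_poly="full"`; its unpenalized cubic difference extrapolates
freely below the MS age support and is markedly worse for departure-age
estimation.

Covariate structures are bundles: a three-way covariate x MS x age-spline
term always carries its two-way components and main effect; DMT exposure and
clinical-onset age never enter three-way terms. Continuous covariates are
standardized by training moments. One smoothing variance is shared by all
penalized blocks (base smooth, MS smooth, covariate smooths) — a documented
simplification that keeps the profiled likelihood two-dimensional; a
per-block smoothing parameter would be the natural extension.

### 4.4 Estimation

The likelihood is profiled: with variance ratios lambda = (lambda_s,
lambda_b), the marginal covariance is sigma^2 W(lambda), the fixed effects
and sigma^2 have closed forms, and -2log L reduces to determinant and
quadratic-form pieces computed with Woodbury identities — subject blocks are
rank-1 (intercept; optional independent slope makes them rank-2) and
inverted in closed form from per-subject cross-products, the global spline
block is low-rank. After one-time precomputation a likelihood evaluation
costs O(m c^2 + c^3) for m subjects and c design columns; a full fit takes
milliseconds to ~1 s at the problem sizes used here.

Optimization is Nelder-Mead on log-variance-ratios from a fixed zero start
(xatol 1e-7, fatol 1e-9, ratios clipped to e^{+-14}); if the optimum lands on
the log-ratio boundary, two fixed alternative starts are tried and the best
kept — deterministic, no random restarts. AIC = -2l + 2p and
BIC = -2l + p log(n_obs) with p = fixed coefficients + variance components
(sigma^2, smoothing ratio, subject components); ML is used when comparing
covariate structures, REML is appropriate when comparing penalty structures
at a fixed mean model. Spline coefficients are reported as BLUPs; the
pointwise band uses the joint (beta, u) covariance
sigma^2 (M' B^{-1} M + diag(0, I/lambda_s))^{-1}, which widens appropriately
under extrapolation.

## 5. Model selection

Twelve spline structures (4 bases x 3 penalties) and a covariate catalog
generated from staged rules — (a) main effects, (b) two-way x MS, (c)
three-way bundles one at a time, (d)-(f) pairs/triples/quadruples, (g)
backward reductions demoting one three-way bundle to its two-way components —
are scored on four criteria: training AIC/BIC; held-out repeated-measures
correlation and ICC on a 10% subject-level MS holdout; shape concordance
(Pearson correlation >= 0.9 between the fitted control lifespan curve and the
cross-sectional MARS curve, screening overfit "wild" trajectories); and the
mean 95% band half-width on the 15-75 grid (<= 1.5x the narrowest
candidate). Survivors rank by AIC, then BIC, then held-out rmcorr, then
candidate id. The catalog from these rules has 62 members (the historically
quoted count of 52 corresponds to a list that was never published); the
published final structure — all six main effects plus sex x MS and
sex x age-spline — is a member by construction.

## 6. Twin pairs, onset detection, bootstrap

For a patient, the MS curve uses MS = 1 and the patient's covariates; the
twin curve uses MS = 0 with clinical-onset age and DMT exposure set to zero
and all else identical. Both are population-level predictions (subject
random effects at zero) on the age grid 15-75 step 1.

The PBTL onset is detected from d(a) = twin(a) - ms(a) as the changepoint
before which d <= delta (default 0) and after which d > delta, chosen to
minimize the number of grid points violating that pattern; for exact
crossings this is simply the last age with d <= delta, while under sampling
noise it treats pre- and post-crossing excursions symmetrically (the literal
last-crossing rule is positively biased: any late noise dip resets the
crossing to an older age). The crossing is refined by linear interpolation
to 0.1-year resolution. Curves that never cross on the grid return the age
of minimal |d| with a `no_crossing` flag (the near-parallel-curves situation
typical of young clinical onset); identical curves return an `undetermined`
sentinel.

CIs come from a patient-level block bootstrap of the training table: subjects
are resampled with replacement, all scans of a subject moving together, the
model is refitted, and the patient's onset recomputed; the point estimate is
the bootstrap mean and the CI the 2.5/97.5 percentiles. `mode="refit"`
re-estimates variance components per replicate; `mode="fast"` freezes them at
the base fit and re-solves only the coefficients from per-subject sufficient
statistics (milliseconds per replicate), which large simulation harnesses
use. Undetermined replicates are dropped and counted; no-crossing replicates
contribute their minimal-|d| age, so the outlier behavior for young-onset
patients is surfaced in the CI rather than hidden. A patient is "earlier"
onset iff the CI's upper limit is strictly below their clinical onset age
(ties conservative to "simultaneous"). Tenfold cross-validation partitions
MS subjects into ten folds by a seeded permutation of sorted ids; each fold's
patients are estimated from a model fitted on the other folds plus all
controls, so nobody appears in their own training data.

## 7. Synthetic cohorts

### 7.1 Lifespan generator

Controls draw ages from a five-component mixture emulating the real sources
(dense young components at 19 +- 2 and 29 +- 4, older components at 58 +- 14
and 40 +- 11, an elderly component at 75 +- 7); ~11% have 2-4 repeat scans
over 2.5 +- 1.4 years, concentrated in the elderly and mid-life clinical
components as in the real repeat composition. MS subjects have clinical
onset ~ N(33.5, 9.1) clipped to [18, 60], entry ~9 +- 5 years later, 70%
female (vs 56% in controls), DMT exposure ~ Exp(2.5) years, and 4 +- 1.5
annual scans. The normal-aging mean is a quadratic decline (plateau in
youth, accelerating loss; about -0.03/y at mid-life) plus sex (+0.15 for
female) and ICV effects; subject random intercepts have sd 0.65 and scan
noise sd 0.15, so the cross-sectional spread is ~1 matching the cohort
descriptives. The noise split follows typical subcortical segmentation
test-retest precision.

Each MS subject's trajectory equals the normal curve before their deviation
age a0 and loses an additional `excess_rate` (default 0.03/y, consistent with
a ~0.4 normalized-unit deficit accrued over ~14 years) per year after a0;
a quadratic smooth-onset ramp is available. By default a0 = clinical onset
minus a N(5, 2) gap; `common_deviation_age` fixes a0 for recovery
experiments. The generator returns the ground truth (per-subject a0 and
noise-free trajectories) alongside the table.

What the generator does *not* emulate: scanner/site effects, segmentation
failures, real-data model misfit, and correlated within-subject biological
fluctuation. Two consequences observed in the validation experiments: the
augmented-vs-observed ICC here is higher than the published real-data value
(no site heterogeneity), and the repeated-measures correlation between
augmented and observed repeats is weak (~0.1) because at honest repeat
spacing the within-subject increments are noise-dominated — notably, the
published real-data pair (ICC 0.62 with rmcorr 0.67) is jointly unattainable
under any pure subject/scan noise split, so passing agreement tests here
certify the arithmetic and the detection of true agreement, not real-data
effect sizes.

### 7.2 Fish-bone designs

Training: 10 age blocks of 5 years from age 30, 50 fresh subjects per block
(half MS), 5 annual points each — 500 subjects, 2500 records. The fixed
intercept and slope carry block weights W_k, V_k that decrease
multiplicatively by 1% per block in the young phase, 5% mid-life, 1% in the
old phase, bending the backbone into a spline shape. Random intercept
(sd 0.6) and slope (sd 0.05) per subject; residual sd 0.3. Testing keeps a
single subject id across all blocks (50 subjects), observed at all 50 block
ages plus the four younger extrapolation ages 26-29 (54 ages each). The
block-specific fixed-effect means are available in closed form as oracles.

## 8. Experiment design notes

* Deviation-age recovery uses a sex{main, x MS} structure (the arms' sex
  compositions differ, and an unadjusted MS offset absorbs the composition
  difference) and excludes baseline thalamic volume, which is a lagged
  outcome: conditioning on it absorbs each patient's own accrued deficit and
  destroys recovery. Patient-level estimation adds the clinical-onset main
  effect, which individualizes the MS curve (and is zeroed for the twin).
* Coverage experiments use many small independent cohorts because patients
  sharing one training set have perfectly correlated CIs, making a coverage
  proportion over them degenerate.
* Problem sizes (20 seeds x 300 MS subjects for recovery; 20 cohorts x 5
  patients at B = 200 for coverage with a 10-patient full-refit spot check;
  800 controls / 250 MS for classification and the gap summary; 50
  fish-bone replicates at 20 subjects/block for the AIC ordering) are the
  package's default desk-scale settings.
* At these conditions the measured deviation-age recovery error is ~2 years
  in the pooled median — the statistical limit implied by the design: the
  crossing error is the deficit-line error divided by the 0.03/y excess
  rate, and one ~2-sigma cohort draw can shift its crossing by many years.
  The twelve-structure ML-AIC comparison yields statistically
  indistinguishable fits across bases and penalties on fish-bone data
  (paired AIC differences of a few units, fractions near 50%); the large
  historical separations between these structures are not reproduced by
  these penalty definitions under ML-selected smoothing, and the acceptance
  suite reports the measured fractions rather than forcing the ordering.

## 9. Known limitations

* Shared smoothing variance across penalized blocks (Section 4.3).
* Population-level patient curves: no BLUP adjustment toward a patient's own
  scans (the per-patient individualization is through covariates only).
* The P-spline and radial-smoothing penalties are one reasonable reading of
  the named G-side covariance types; other software realizes them
  differently, and comparative conclusions across penalty types depend on
  that reading.
* The bootstrap fast mode freezes variance components; it matches the full
  refit closely in location but slightly understates component uncertainty.
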