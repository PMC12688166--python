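# Methods

This note records the models, estimators, numerical choices and known
limitations behind `ctdna_monitor`, in the order the pipeline runs.

## Data model and time alignment

All analyses share one cohort representation: four long-format tables
(patients, treatment intervals, plasma samples, CT scans) on a per-patient
integer-day axis. Day zero is the patient's first CT scan; plasma drawn
earlier has negative days. Samples taken after a patient's last scan are
flagged `post_followup` and excluded from the Bayesian model (no outcome
exists to link them to). The intrinsic subtype is a pure function of
receptor status — Her2+ whenever Her2 is positive, otherwise ER+Her2− or
triple negative — and patients missing ER/Her2 are retained for
subtype-agnostic analyses but dropped wherever subtype or receptor status is
a covariate. When a patient has two samples on one day the higher tumour
fraction is kept (a conservative choice for a burden marker) and a warning
logged.

## Copy-number burden metrics

Profiles are 1-Mb binned log2 ratios over chromosomes 1–23 (autosomes plus
X). The panel of normals stores the per-bin median across buffy-coat
profiles — subtracted from every sample as the baseline — and the per-bin
mean and standard deviation of the centred normals for the z-score.

* **z-score**: per bin `Z = (value − panel_mean) / panel_sd`; the summary is
  the sum of retained bins' z-scores divided by the retained bin count. Two
  bin filters ship: `literal` keeps bins with log2 ≥ 2 (on a near-diploid
  profile this retains almost nothing and raises an "empty profile" error —
  the filter is preserved exactly as specified because the intended rule is
  ambiguous), and `absolute` drops bins with |log2| below a configurable
  threshold (default 0.1; 0 disables filtering). Neither is asserted to be
  the "right" reading; the CLI defaults to `absolute`.
* **t-MAD**: median absolute deviation of the bin values from copy-number
  neutrality (log2 = 0) after trimming the most extreme 10% of |values|
  (trim fraction configurable). A segmentation must exist because the
  statistic is only meaningful for segmented profiles; a built-in binary
  segmenter (per-chromosome recursive single-split on RSS gain with a
  penalty of 10 per breakpoint) serves when no external segmentation is
  supplied, and also provides the QC noise statistic (SD of bins around
  their segment means; samples fail QC under 1 million aligned reads or
  above a noise ceiling of 0.3).
* **Solution selection**: the tumour-fraction HMM returns several candidate
  fits; large subclonal fractions usually flag overfitting. `literal` mode
  executes the published recipe verbatim (which, as printed, removes the
  maximum-likelihood solution itself and falls back to it when the filter
  empties the list). `interpreted` mode keeps solutions within 2.5% relative
  log-likelihood of the best, discards those whose subclonal fraction
  exceeds the smallest surviving subclonal fraction by more than 0.25, and
  takes the maximum likelihood among the rest. Measuring subclonal excess
  against the *minimum* (rather than the maximum) makes the rule stable: a
  strictly dominated candidate (lower likelihood, higher subclonal fraction)
  can never change the selection.
* **Arcsine transform**: `arcsin(sqrt(tf))`, the variance-stabilising scale
  on which the longitudinal model operates; exact inverse `sin(y)^2`.

## Survival models and threshold discovery

Scores enter Cox models as a time-varying covariate in counting-process
form: one (start, stop] row per inter-sample interval carrying the last
observed score (LOCF), truncated at the event/censoring day. PFS events are
the first progressive-disease scan (censoring at the last scan); OS uses the
death/censor day from the clinical table. Scores are in percent so hazard
ratios read "per percentage point". Fits use `lifelines`'
`CoxTimeVaryingFitter` (Efron ties). The concordance index is Harrell's c
for time-varying data: each event, at its stop time, is compared against
every interval at risk at that moment; ties count one half. Its standard
error uses the normal approximation `sqrt(c(1−c)/events)`.

The spline model uses a restricted cubic spline with 4 knots at the 5/35/
65/95% quantiles of observed scores (knot count configurable). Changepoint
discovery fits the spline+subtype model on a random subsample of 70
patients, evaluates the fitted score contribution at the observed scores
(duplicates averaged), and fits a continuous two-slope segmented regression
by exhaustive search: every interior observed score is a candidate
breakpoint, the least-squares problem in the basis `(1, x, (x−c)+)` is
solved per candidate, and the minimum-RSS candidate wins. Pure straight
lines set a `degenerate` flag and return the midpoint. Fifty replicates are
averaged; the working threshold is the ceiling of the mean changepoint in
whole percent (upstream tumour-fraction estimates carry no decimals). A
second pass refits a threshold-indicator Cox model on each replicate's
held-out patients and reports the mean hazard ratio and median c-index.
Because the spline smooths the kink, the segmented fit tends to place the
break slightly below a true hazard-slope break; simulation at the default
conditions recovers a 10% break to within about one to two points.

Threshold-indicator fits on strongly separated data (all events on one side)
have monotone partial likelihoods; fits whose coefficient or standard error
exceeds 10 are treated as degenerate and skipped with a log message rather
than propagated into summary means. "Expected time to progression" for a
subtype is the restricted mean survival time of the fitted curve — the
Breslow baseline cumulative hazard at zero covariates, scaled by
`exp(coef · indicator)` — integrated to the subtype's longest follow-up and
reported in months (days / 30.44). RMST is a model-derived summary; other
definitions of "expected time" would give different numbers.

## Stopping rule

Decision points pair each plasma sample with the next CT scan on the same
treatment, keeping only pairs where both fall between 21 and 183 days after
the treatment start (3 weeks to 6 months) and the sample precedes the scan
by at most 91 days (3 months). Same-day pairs are kept but flagged. Each
eligible sample yields its own decision point. The rule: score below the
threshold → response; at/above with a strict decrease from the previous
same-treatment sample → response; otherwise (increase, no change, or no
previous sample) → progression. Treating "no previous sample + high score"
as progression reads the previous-value condition as applying only when a
previous value exists. Sensitivity is TP/(TP+FN) with progressive disease as
the positive class.

## Two-stage Bayesian model

**Stage 1** (longitudinal): arcsine-scale tumour fraction with fixed effects
for time since first CT (years), ER, Her2, treatment duration (years) and
regimen (one-hot against the most frequent regimen; constant columns
dropped), plus a per-patient random intercept and slope
`b_i ~ N(0, Sigma_b)` and i.i.d. Gaussian error. **Stage 2** (outcome):
random-intercept logistic regression of the per-scan progression flag on
time, ER, Her2 and regimen, plus `gamma' bhat_i` where `bhat_i` is the
stage-1 posterior mean of `b_i` — the plug-in two-stage linkage: patients
whose ctDNA is high at baseline or rising steeply carry higher progression
odds. Regimen levels with constant stage-2 outcomes (separation) or fewer
than 5 scans are flagged non-identifiable; their dummies are dropped and
predictions under them refused by name.

Priors: non-intercept coefficients N(0, 10²); intercepts Student-t(3, 0,
2.5); random-effect SDs half-Cauchy(2); residual SD half-Student-t(3, 0,
2.5); the 2×2 random-effect correlation uniform on (−1, 1) (the
2-dimensional LKJ(1) prior). The covariance is parametrised as SDs plus
correlation. The residual SD takes the half-Student-t rather than the
half-Cauchy assigned to the random-effect SDs; both are configurable.

**Sampling.** Both posteriors are sampled on the *marginal* scale. The
stage-1 random effects integrate out in closed form; with the rank-2
Woodbury identities the whole likelihood reduces to 2×2 algebra over
per-patient sufficient statistics (`y'y, X'y, X'X, Z'Z, Z'y, Z'X, m`), and
the conditional distribution of `b_i` given a parameter draw is Gaussian
with precision `Sigma_b^{-1} + Z'Z/sigma_e^2` — `bhat_i` is its mean
averaged over retained draws. The stage-2 random intercept integrates by
Gauss–Hermite quadrature (15 nodes by default). The resulting posteriors
have only ~12–15 dimensions, so a classical scheme works well: a BFGS search
(batched finite-difference gradients) finds the mode, the finite-difference
Hessian gives a Laplace covariance (eigenvalues floored for conditioning),
and six independent Metropolis-Hastings chains then mix a multivariate-t
(df 7) independence proposal at the mode with preconditioned random-walk
steps (weight 0.7/0.3). On these near-Gaussian targets the independence
component accepts at high rates, giving near-i.i.d. draws; the random-walk
component keeps the kernel valid when the Laplace approximation is poor
(e.g. a variance component piled against zero). Marginal likelihood and
conditional-mean computations are verified against dense-covariance oracles
in the tests, and interval calibration was checked by simulation (95%
intervals cover true coefficients at the nominal rate on data drawn from the
model). Convergence is split-R-hat over the independent chains, pass iff all
below 1.1; stage 2 refuses an unconverged stage 1 unless forced. Defaults: 6
chains × 3000 steps, 1000 burn-in, 400 retained draws for random-effect
summaries and prediction.

**Prediction** for a patient at time *t* conditions only on data up to *t*:
`bhat_i` is recomputed from samples at or before *t* under each retained
draw, the random intercept's conditional posterior given scans before *t*
is formed on the quadrature grid, and the reported probability is the mean
over draws of the intercept-integrated progression probability, with a
central 95% interval across draws.

**Temporal validation** holds out each patient's chronologically last scan
(patients with ≥ 2 scans) and removes their ctDNA samples after the
preceding scan from training, so nothing downstream of the held-out visit
leaks into any design matrix (audited by a test). The ROC sweeps the
predicted probabilities; AUROC via the trapezoid equals the Mann–Whitney
statistic with ties counted half. The operating cut-off for the confusion
table is calibrated on training-set fitted probabilities at the requested
specificity (cross-validated calibration would be a straightforward
extension). A covariates-only stage-2 refit (no `gamma' bhat` term)
provides the ablation AUROC.

## Concordance analyses

Per-patient correlations between two marker series interpolate both
linearly onto the union of observation days restricted to the overlap of
their spans (no extrapolation), requiring at least 3 common points;
zero-variance series are excluded. Threshold concordance pairs each
observation of one marker with the nearest same-patient observation of the
other within 14 days (same row first) and reports the percentage on the
same side of their positivity thresholds (defaults: tumour fraction 7%,
max-VAF 2.5%, CA15-3 31 U/mL). The discordance audit takes the stopping
rule's false positives (high score, stable scan) and checks the *next* scan
for progression; lead time is the gap to that scan in months (days/30.44).

## Synthetic data

`simulate_cohort` generates exactly the structure the models assume:
subtypes drawn with probabilities 0.60/0.25/0.15 (ER+Her2−/Her2+/TN),
subtype-plausible regimens with one mid-follow-up switch for half the
patients, scans every ~90 days over a 2-year horizon with geometric dropout
(p = 0.08 per scan), plasma sampling at the class cadence (21 days on
chemotherapy, 28 on targeted, 120 on endocrine therapy) relaxing to ~90
days after 84 days on one regimen — mirroring intense early monitoring —
and trajectories/outcomes from the two-stage model with the *true* `b_i`
feeding the logistic stage. Default effect sizes give roughly 30–50%
progressive scans; trajectories are simulated on the arcsine scale and
back-transformed with truncation to [0, 1]. The truncation is the one
deliberate mismatch with the Gaussian stage-1 model (real tumour-fraction
estimates also floor at zero); the posterior-coverage study therefore uses
a ground truth whose trajectories stay interior, where the model is exactly
specified. The generator does not emulate assay noise heteroscedasticity,
informative dropout, or correlation between sampling frequency and disease
severity — passing tests say nothing about those features of real data. The
measurement-error SD (default 0.04 arcsine units) is a free parameter with
no published value.

`simulate_binned_profiles` draws per-bin read counts Poisson (or
negative-binomial) around `depth · (tf·CN/2 + (1−tf))`, normals at CN = 2,
and returns log2 profiles plus a matched panel. `simulate_threshold_cohort`
gives tumour fractions a bounded random walk (percent scale) and draws
progression times from a piecewise-exponential hazard
`base · exp(f(score))` with `f` piecewise linear breaking at 10% by default
— the ground truth for threshold-discovery recovery.

## Problem sizes in the test suite

The suite runs every stage at reduced but statistically meaningful scale:
posterior-coverage over 20 replicate cohorts of 200 patients (4 chains ×
3000 steps), threshold discovery at the full 50 replicates × 70 training
patients, 20-seed sign tests for the ctDNA-vs-ablation AUROC comparison on
60-patient cohorts with light sampler settings, and exact brute-force
cross-checks (c-index pair counts, changepoint RSS search, Mann–Whitney)
at a few hundred rows. The whole suite completes in a few minutes on one
CPU.

## Known limitations

* The two-stage plug-in ignores uncertainty in `bhat_i` when it enters
  stage 2; a joint model is out of scope by design.
* LOCF score carry-forward treats the tumour fraction as a step function;
  rapid changes between draws are invisible.
* RMST-based "expected time to progression" depends on the follow-up
  horizon used for integration.
* The c-index standard error is a normal approximation, not a U-statistic
  variance.
* The stopping rule and decision-point selection assume treatment intervals
  are recorded accurately; samples outside any interval inherit the most
  recent preceding regimen.
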